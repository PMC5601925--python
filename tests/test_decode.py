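import numpy as np
import pandas as pd
import pytest

from tetrascreen import coding
from tetrascreen.decode import (DECOY, DecodeParams, DecodeResult, call_hits,
                                compute_frequencies, concordance, decode_cells)
from tetrascreen.errors import (ConfigurationError, EmptyInputError, ValidationError)
from tetrascreen.events import EventTable
from tetrascreen.pipeline import gate_cd8
from tetrascreen.profiling import logicle_transform
from tetrascreen.synthetic import (ExperimentSpec, default_tumour_spec,
                                   simulate_experiment)


def brute_force_decode(trans, reporters, scheme, threshold, cutoff):
    """Independent oracle: test every cell against every 3-subset of reporters.

    A cell is assigned to a code iff all in-code channels exceed the
    threshold and the dimmest in-code channel clears the brightest
    out-of-code channel by the separation cutoff; exactly one code may
    qualify.  Unused codes map to the decoy sentinel.
    """
    all_codes = coding.enumerate_codes(reporters, 3)
    inverse = {frozenset(c): scheme.decode_table.get(frozenset(c), DECOY)
               for c in all_codes}
    out = np.full(trans.shape[0], "", dtype=object)
    cols = {ch: i for i, ch in enumerate(reporters)}
    for i in range(trans.shape[0]):
        row = trans[i]
        winners = []
        for code in all_codes:
            inside = [row[cols[c]] for c in code]
            outside = [row[cols[c]] for c in reporters if c not in code]
            if min(inside) > threshold and min(inside) - max(outside) >= cutoff:
                winners.append(code)
        if len(winners) == 1:
            out[i] = inverse[frozenset(winners[0])]
    return out


@pytest.fixture(scope="module")
def cd8_noise_free(noise_free_sim):
    ev = noise_free_sim["tumour"]
    return ev.filter((ev.truth["population"] == "cd8_t").to_numpy())


@pytest.fixture(scope="module")
def cd8_noisy(tumour_events):
    ev = tumour_events
    return ev.filter((ev.truth["population"] == "cd8_t").to_numpy())


class TestDecodeCells:
    def test_noise_free_exact(self, cd8_noise_free, schemes, panel, logicle):
        res = decode_cells(cd8_noise_free, schemes[0],
                           DecodeParams(positivity_threshold=1.0),
                           panel.reporter_labels, logicle)
        truth = cd8_noise_free.truth["antigen"].to_numpy()
        np.testing.assert_array_equal(res.antigen, truth)

    def test_equivalent_to_brute_force_oracle(self, cd8_noisy, schemes, panel, logicle):
        sub = cd8_noisy.take(np.arange(min(4000, cd8_noisy.n_events)))
        params = DecodeParams(positivity_threshold=1.2, separation_cutoff=0.5)
        res = decode_cells(sub, schemes[0], params, panel.reporter_labels, logicle)
        trans = logicle_transform(sub.intensities[panel.reporter_labels], logicle)
        oracle = brute_force_decode(trans.to_numpy(), panel.reporter_labels,
                                    schemes[0], 1.2, 0.5)
        np.testing.assert_array_equal(res.antigen, oracle)

    def test_two_channels_high_unassigned(self, panel, schemes, logicle):
        df = pd.DataFrame(np.zeros((1, 9)), columns=panel.reporter_labels)
        code = schemes[0].code_map["mLama4"]
        df[code[0]] = 1000.0
        df[code[1]] = 1000.0
        res = decode_cells(EventTable(df), schemes[0],
                           DecodeParams(positivity_threshold=1.0),
                           panel.reporter_labels, logicle)
        assert res.antigen[0] == ""

    def test_four_way_tie_unassigned(self, panel, schemes, logicle):
        df = pd.DataFrame(np.zeros((1, 9)), columns=panel.reporter_labels)
        for ch in panel.reporter_labels[:4]:
            df[ch] = 1000.0
        res = decode_cells(EventTable(df), schemes[0],
                           DecodeParams(positivity_threshold=1.0),
                           panel.reporter_labels, logicle)
        assert res.antigen[0] == ""

    def test_empty_scheme_rejected(self, cd8_noise_free, panel):
        with pytest.raises((ConfigurationError, ValidationError)):
            decode_cells(cd8_noise_free, coding.CodingScheme("A", {}))

    def test_counts_conserved(self, cd8_noisy, schemes, panel, logicle):
        res = decode_cells(cd8_noisy, schemes[0], DecodeParams(),
                           panel.reporter_labels, logicle)
        n_assigned = int(res.assigned_mask.sum())
        n_decoy = int((res.antigen == DECOY).sum())
        n_unassigned = int((res.antigen == "").sum())
        assert n_assigned + n_decoy + n_unassigned == cd8_noisy.n_events

    def test_hit_count_monotone_in_separation_cutoff(self, cd8_noisy, schemes,
                                                     panel, logicle):
        counts = []
        for cut in (0.1, 0.5, 1.5, 3.0):
            res = decode_cells(cd8_noisy, schemes[0],
                               DecodeParams(separation_cutoff=cut,
                                            positivity_threshold=1.2),
                               panel.reporter_labels, logicle)
            counts.append(int(res.assigned_mask.sum()))
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestComputeFrequencies:
    def _result(self, antigens):
        n = len(antigens)
        return DecodeResult(antigen=np.array(antigens, dtype=object),
                            top3=np.empty((n, 3), dtype=object),
                            separation=np.ones(n), threshold=1.0, config_id="A")

    def test_simple_arithmetic(self):
        res = self._result(["x"] * 10 + [""] * 990)
        df = compute_frequencies(res)
        assert df.set_index("antigen").loc["x", "frequency"] == pytest.approx(0.01)

    def test_zero_assigned(self):
        res = self._result([""] * 100)
        df = compute_frequencies(res, antigens=["x"])
        assert df["frequency"].sum() == 0
        assert df.attrs["unassigned_fraction"] == 1.0

    def test_frequencies_plus_unassigned_sum_to_one(self):
        res = self._result(["x"] * 5 + ["y"] * 10 + [DECOY] * 2 + [""] * 83)
        df = compute_frequencies(res, antigens=["x", "y"])
        assert df["frequency"].sum() + df.attrs["unassigned_fraction"] == pytest.approx(1.0)
        assert df.attrs["decoy_count"] == 2

    def test_empty_input_rejected(self):
        with pytest.raises(EmptyInputError):
            compute_frequencies(self._result([]), n_cd8=0)

    def test_replicate_recovery_within_3_sem(self, schemes, panel, noise, logicle):
        # oracle: the generator's configured tumour frequency (0.102)
        freqs = []
        for rep in range(5):
            tis = default_tumour_spec(20_000)
            sim = simulate_experiment(ExperimentSpec([tis]), schemes[0], noise,
                                      seed=600 + rep, panel=panel)
            cd8, _ = gate_cd8(sim["A"]["tumour"], panel, logicle)
            res = decode_cells(cd8, schemes[0], DecodeParams(),
                               panel.reporter_labels, logicle)
            df = compute_frequencies(res).set_index("antigen")
            freqs.append(float(df.loc["mLama4", "frequency"]))
        sem = np.std(freqs, ddof=1) / np.sqrt(len(freqs))
        assert abs(np.mean(freqs) - 0.102) < 3 * max(sem, 1e-4)


class TestCallHits:
    def _freq_table(self, mapping, n=10_000):
        df = pd.DataFrame([{"antigen": a, "count": int(f * n), "frequency": f}
                           for a, f in mapping.items()])
        df.attrs["n_cd8"] = n
        return df

    def test_boundary_is_strict(self):
        hits = call_hits({"tumour": self._freq_table({"x": 0.0015, "y": 0.00151})})
        by = hits.set_index("antigen")
        assert not by.loc["x", "is_hit"]
        assert by.loc["y", "is_hit"]

    def test_wild_type_all_zero(self):
        hits = call_hits({"spleen": self._freq_table({"x": 0.0, "y": 0.0})})
        assert not hits["is_hit"].any()

    def test_consistent_requires_all_tissues(self):
        tables = {
            "tumour": self._freq_table({"x": 0.01, "y": 0.01}),
            "spleen": self._freq_table({"x": 0.01, "y": 0.001}),
        }
        hits = call_hits(tables)
        assert hits[hits["antigen"] == "x"]["consistent_hit"].all()
        assert not hits[hits["antigen"] == "y"]["consistent_hit"].any()

    def test_min_tissues_override(self):
        tables = {
            "tumour": self._freq_table({"y": 0.01}),
            "spleen": self._freq_table({"y": 0.001}),
        }
        hits = call_hits(tables, DecodeParams(min_tissues=1))
        assert hits["consistent_hit"].all()

    def test_hit_count_monotone_in_cutoff(self):
        table = self._freq_table({"a": 0.001, "b": 0.002, "c": 0.01, "d": 0.2})
        counts = [call_hits({"t": table}, DecodeParams(hit_cutoff=c))["is_hit"].sum()
                  for c in (0.0005, 0.0015, 0.005, 0.05)]
        assert all(x >= y for x, y in zip(counts, counts[1:]))


class TestConcordance:
    def _hits(self, flags):
        return pd.DataFrame([{"antigen": a, "tissue": "tumour", "arm": "isotype",
                              "frequency": 0.01 if h else 0.0, "n_cells": 1000,
                              "is_hit": h, "consistent_hit": h}
                             for a, h in flags.items()])

    def test_both_call_concordant(self):
        out = concordance(self._hits({"mLama4": True}), self._hits({"mLama4": True}))
        assert out["concordant"].all()

    def test_single_config_call_not_concordant(self):
        out = concordance(self._hits({"decoy": True}), self._hits({"decoy": False}))
        assert not out["concordant"].any()

    def test_mismatched_sets_rejected(self):
        with pytest.raises(ValidationError):
            concordance(self._hits({"a": True}), self._hits({"b": True}))

    def test_dual_config_suppresses_false_positives(self, schemes, panel, logicle):
        # oracle: repeated-decode simulation of junk cells carrying random
        # reporter triples (an artificial false-positive channel); each
        # staining configuration sees an independent junk draw
        rng = np.random.default_rng(8)
        n_cd8, n_junk = 20_000, 2_100
        reporters = panel.reporter_labels

        def junk_hits(scheme):
            df = pd.DataFrame(np.zeros((n_cd8, 9)), columns=reporters)
            rows = np.arange(n_junk)
            for r in rows:
                for ch in rng.choice(reporters, 3, replace=False):
                    df.loc[r, ch] = 1000.0
            res = decode_cells(EventTable(df), scheme,
                               DecodeParams(positivity_threshold=1.0),
                               reporters, logicle)
            freqs = compute_frequencies(res, n_cd8=n_cd8,
                                        antigens=sorted(scheme.code_map))
            return call_hits({"tumour": freqs})

        hits_a = junk_hits(schemes[0])
        hits_b = junk_hits(schemes[1])
        single_rate = int(hits_a["is_hit"].sum())
        out = concordance(hits_a, hits_b)
        assert single_rate > 0  # the junk channel does produce single-config calls
        assert int(out["concordant"].sum()) < single_rate


class TestDecoyQC:
    def test_no_decoy_hits_at_default_noise(self, cd8_noisy, schemes, panel, logicle):
        res = decode_cells(cd8_noisy, schemes[0], DecodeParams(),
                           panel.reporter_labels, logicle)
        assert res.decoy_rate == 0.0
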