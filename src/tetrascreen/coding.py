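"""Antigen panels and combinatorial code books.

Each antigen is detected by a tetramer labelled with an unordered triple of
metal-tagged streptavidins drawn from nine reporter channels, giving
C(9,3) = 84 addressable codes; samples are multiplexed with unordered pairs
drawn from six barcode channels (five Pd masses plus one lanthanide-linked
mass, modeled here as In113).
"""
from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import CapacityError, ConfigurationError, ValidationError

# channel roles
ROLE_REPORTER = "tetramer_reporter"
ROLE_PHENOTYPE = "phenotype"
ROLE_LINEAGE = "lineage"
ROLE_BARCODE = "barcode"
ROLE_BEAD = "bead"
ROLE_DNA = "dna"
ROLE_VIABILITY = "viability"

CATEGORIES = ("known", "predicted", "control")


@dataclass(frozen=True)
class MetalChannel:
    """A single acquisition channel: metal label, mass, functional role."""

    label: str
    mass: int
    role: str
    marker: str | None = None  # antibody target for phenotype/lineage channels


class Panel:
    """An ordered collection of :class:`MetalChannel` with unique labels."""

    def __init__(self, channels: Sequence[MetalChannel]):
        labels = [c.label for c in channels]
        if len(set(labels)) != len(labels):
            raise ValidationError("channel labels must be unique within a panel")
        markers = [c.marker for c in channels if c.marker is not None]
        if len(set(markers)) != len(markers):
            raise ValidationError("marker names must be unique within a panel")
        self.channels: tuple[MetalChannel, ...] = tuple(channels)
        self._by_label = {c.label: c for c in channels}
        self._by_marker = {c.marker: c for c in channels if c.marker}

    def labels(self, role: str | None = None) -> list[str]:
        return [c.label for c in self.channels if role is None or c.role == role]

    def markers(self, role: str | None = None) -> list[str]:
        return [c.marker for c in self.channels if c.marker and (role is None or c.role == role)]

    def label_for(self, marker_or_label: str) -> str:
        if marker_or_label in self._by_label:
            return marker_or_label
        if marker_or_label in self._by_marker:
            return self._by_marker[marker_or_label].label
        raise ConfigurationError(f"unknown channel or marker: {marker_or_label!r}")

    def labels_for(self, names: Iterable[str]) -> list[str]:
        return [self.label_for(n) for n in names]

    @property
    def reporter_labels(self) -> list[str]:
        return self.labels(ROLE_REPORTER)

    @property
    def barcode_labels(self) -> list[str]:
        return self.labels(ROLE_BARCODE)

    @property
    def bead_labels(self) -> list[str]:
        return self.labels(ROLE_BEAD)

    def __iter__(self):
        return iter(self.channels)

    def __len__(self) -> int:
        return len(self.channels)


def default_channels() -> Panel:
    """The default 45-channel acquisition panel.

    Reporter metals Gd157/Tb159/Dy163/Tm169/Yb173 carry the published example
    codes; the remaining four reporters and all marker-mass assignments are
    arbitrary but fixed.
    """
    ch: list[MetalChannel] = []
    # 9 tetramer reporters
    for lab, mass in [("La139", 139), ("Pr141", 141), ("Nd143", 143), ("Sm147", 147),
                      ("Gd157", 157), ("Tb159", 159), ("Dy163", 163), ("Tm169", 169),
                      ("Yb173", 173)]:
        ch.append(MetalChannel(lab, mass, ROLE_REPORTER))
    # 6 sample barcodes: five Pd + one lanthanide-linked mass (modeled as In113)
    for lab, mass in [("Pd102", 102), ("Pd104", 104), ("Pd106", 106),
                      ("Pd108", 108), ("Pd110", 110), ("In113", 113)]:
        ch.append(MetalChannel(lab, mass, ROLE_BARCODE))
    # EQ four-element calibration bead channels
    for lab, mass in [("Ce140", 140), ("Eu151", 151), ("Eu153", 153),
                      ("Ho165", 165), ("Lu175", 175)]:
        ch.append(MetalChannel(lab, mass, ROLE_BEAD))
    ch.append(MetalChannel("Ir191", 191, ROLE_DNA, "DNA1"))
    ch.append(MetalChannel("Ir193", 193, ROLE_DNA, "DNA2"))
    ch.append(MetalChannel("Pt195", 195, ROLE_VIABILITY, "cisplatin"))
    for lab, mass, marker in [("Y89", 89, "CD45"), ("Nd142", 142, "CD19"),
                              ("Nd144", 144, "TCRb"), ("Nd145", 145, "CD90"),
                              ("Nd146", 146, "CD8"), ("Nd148", 148, "CD4")]:
        ch.append(MetalChannel(lab, mass, ROLE_LINEAGE, marker))
    for lab, mass, marker in [("Nd150", 150, "PD-1"), ("Sm152", 152, "KLRG-1"),
                              ("Gd156", 156, "Sca-1"), ("Gd158", 158, "Tim-3"),
                              ("Gd160", 160, "ICOS"), ("Dy161", 161, "CD39"),
                              ("Dy162", 162, "CD27"), ("Dy164", 164, "CD160"),
                              ("Er166", 166, "GITR"), ("Er167", 167, "Lag-3"),
                              ("Er168", 168, "CD25"), ("Er170", 170, "CD38"),
                              ("Yb171", 171, "CD127"), ("Yb172", 172, "CD44"),
                              ("Yb174", 174, "CD62L"), ("Yb176", 176, "CXCR3")]:
        ch.append(MetalChannel(lab, mass, ROLE_PHENOTYPE, marker))
    panel = Panel(ch)
    assert len(panel.reporter_labels) == 9 and len(panel.barcode_labels) == 6
    return panel


# --------------------------------------------------------------------- panel
@dataclass(frozen=True)
class AntigenEntry:
    antigen_id: str
    peptide: str
    category: str  # known | predicted | control


class AntigenPanel:
    """The list of screened antigens plus control entries."""

    def __init__(self, entries: Sequence[AntigenEntry]):
        ids = [e.antigen_id for e in entries]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate antigen_id(s): {dupes}")
        for e in entries:
            if e.category not in CATEGORIES:
                raise ValidationError(f"unknown category {e.category!r} for {e.antigen_id}")
        self.entries: tuple[AntigenEntry, ...] = tuple(entries)

    @property
    def screened_ids(self) -> list[str]:
        return [e.antigen_id for e in self.entries if e.category != "control"]

    @property
    def control_ids(self) -> list[str]:
        return [e.antigen_id for e in self.entries if e.category == "control"]

    @property
    def screened_count(self) -> int:
        return len(self.screened_ids)

    @property
    def antigen_ids(self) -> list[str]:
        return [e.antigen_id for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)


def build_default_panel(candidate_table: pd.DataFrame | None = None) -> AntigenPanel:
    """Build the antigen panel from a candidate table (default: shipped fixture).

    The table needs columns ``antigen_id``, ``peptide``, ``category``.
    Control entries (e.g. SIINFEKL) are kept but excluded from the screened
    count.
    """
    if candidate_table is None:
        ref = importlib.resources.files("tetrascreen.data") / "candidate_epitopes.csv"
        with ref.open("r") as fh:
            candidate_table = pd.read_csv(fh, comment="#")
    required = {"antigen_id", "peptide", "category"}
    if not required.issubset(candidate_table.columns):
        raise ValidationError(f"candidate table needs columns {sorted(required)}")
    entries = [AntigenEntry(str(r.antigen_id), str(r.peptide), str(r.category))
               for r in candidate_table.itertuples()]
    return AntigenPanel(entries)


# ----------------------------------------------------------------- codebooks
def enumerate_codes(channels: Sequence[str] | int, code_size: int) -> list[tuple[str, ...]]:
    """All size-``code_size`` subsets of ``channels``, sorted, in lexicographic order.

    ``channels`` may be an integer n, standing for labels ``ch1..chn``.
    """
    if isinstance(channels, (int, np.integer)):
        channels = [f"ch{i}" for i in range(1, int(channels) + 1)]
    channels = sorted(channels)
    if not 1 <= code_size <= len(channels):
        raise ValidationError(
            f"code_size must be in [1, {len(channels)}], got {code_size}")
    return [tuple(c) for c in combinations(channels, code_size)]


@dataclass
class CodingScheme:
    """Bijection antigen_id -> sorted 3-subset of reporter channel labels."""

    config_id: str
    code_map: dict[str, tuple[str, ...]]
    capacity: int = comb(9, 3)
    code_size: int = 3

    def __post_init__(self) -> None:
        for aid, code in self.code_map.items():
            if len(code) != self.code_size:
                raise ValidationError(f"code for {aid} has {len(code)} channels")
            if tuple(sorted(code)) != tuple(code):
                self.code_map[aid] = tuple(sorted(code))
        codes = list(self.code_map.values())
        if len(set(codes)) != len(codes):
            raise ValidationError("codes must be distinct (injective code_map)")
        if len(codes) > self.capacity:
            raise CapacityError(f"{len(codes)} codes exceed capacity {self.capacity}")

    @property
    def decode_table(self) -> dict[frozenset, str]:
        return {frozenset(code): aid for aid, code in self.code_map.items()}

    def unused_codes(self, channels: Sequence[str]) -> list[tuple[str, ...]]:
        used = set(self.code_map.values())
        return [c for c in enumerate_codes(channels, self.code_size) if c not in used]


#: published example codes (configuration A)
PINNED_CODES: dict[str, tuple[str, ...]] = {
    "mLama4": ("Gd157", "Tb159", "Yb173"),
    "mAlg8": ("Dy163", "Tm169", "Yb173"),
}


def assign_codes(
    panel: AntigenPanel,
    channels: Panel | Sequence[str],
    config_id: str,
    seed: int,
    base_scheme: CodingScheme | None = None,
    max_shared: int = 1,
    pinned: Mapping[str, tuple[str, ...]] | None = None,
) -> CodingScheme:
    """Randomly assign distinct 3-channel codes to every antigen in ``panel``.

    Deterministic under ``seed``.  When ``base_scheme`` is given (building the
    second staining configuration), each antigen's new code may share at most
    ``max_shared`` channels with its base code.
    """
    reporters = channels.reporter_labels if isinstance(channels, Panel) else list(channels)
    if len(reporters) < 3:
        raise ConfigurationError("need at least 3 reporter channels")
    all_codes = enumerate_codes(reporters, 3)
    antigens = panel.antigen_ids
    if len(antigens) > len(all_codes):
        raise CapacityError(
            f"panel of {len(antigens)} exceeds code-book capacity {len(all_codes)}")

    rng = np.random.default_rng(seed)
    code_map: dict[str, tuple[str, ...]] = {}
    pool = list(all_codes)
    if pinned:
        for aid, code in pinned.items():
            code = tuple(sorted(code))
            if aid not in antigens:
                raise ConfigurationError(f"pinned antigen {aid!r} not in panel")
            if code not in pool:
                raise ConfigurationError(f"pinned code {code} not available")
            code_map[aid] = code
            pool.remove(code)

    remaining = [a for a in antigens if a not in code_map]
    for attempt in range(100):
        order = list(pool)
        rng.shuffle(order)
        trial: dict[str, tuple[str, ...]] = {}
        ok = True
        for aid in remaining:
            placed = False
            for i, code in enumerate(order):
                if base_scheme is not None and aid in base_scheme.code_map:
                    shared = len(set(code) & set(base_scheme.code_map[aid]))
                    if shared > max_shared:
                        continue
                trial[aid] = code
                order.pop(i)
                placed = True
                break
            if not placed:
                ok = False
                break
        if ok:
            code_map.update(trial)
            break
    else:  # pragma: no cover - probabilistically unreachable at defaults
        raise CapacityError("could not satisfy code-separation constraint")

    return CodingScheme(config_id=config_id, code_map=code_map,
                        capacity=len(all_codes))


def default_schemes(
    antigen_panel: AntigenPanel | None = None,
    channels: Panel | None = None,
    seed: int = 0,
) -> tuple[CodingScheme, CodingScheme]:
    """Paired configuration-A/B schemes with the published example codes pinned in A."""
    antigen_panel = antigen_panel or build_default_panel()
    channels = channels or default_channels()
    pinned = {k: v for k, v in PINNED_CODES.items() if k in antigen_panel.antigen_ids}
    scheme_a = assign_codes(antigen_panel, channels, "A", seed, pinned=pinned)
    scheme_b = assign_codes(antigen_panel, channels, "B", seed + 1, base_scheme=scheme_a)
    return scheme_a, scheme_b


# ------------------------------------------------------------------ barcodes
@dataclass
class BarcodeScheme:
    """sample_id -> sorted 2-subset of barcode channel labels."""

    code_map: dict[str, tuple[str, str]]
    code_size: int = 2

    def __post_init__(self) -> None:
        for sid, code in self.code_map.items():
            if len(code) != self.code_size:
                raise ValidationError(f"barcode for {sid} must have {self.code_size} channels")
            self.code_map[sid] = tuple(sorted(code))
        codes = list(self.code_map.values())
        if len(set(codes)) != len(codes):
            raise ValidationError("barcodes must be distinct")

    @property
    def decode_table(self) -> dict[frozenset, str]:
        return {frozenset(code): sid for sid, code in self.code_map.items()}

    @property
    def channels(self) -> list[str]:
        return sorted({c for code in self.code_map.values() for c in code})


def default_barcode_scheme(sample_ids: Sequence[str],
                           channels: Panel | Sequence[str] | None = None) -> BarcodeScheme:
    """Assign 2-of-6 barcode codes to samples in lexicographic code order."""
    if channels is None:
        channels = default_channels()
    barcodes = channels.barcode_labels if isinstance(channels, Panel) else list(channels)
    codes = enumerate_codes(barcodes, 2)
    if len(sample_ids) > len(codes):
        raise CapacityError(
            f"{len(sample_ids)} samples exceed barcode capacity {len(codes)}")
    return BarcodeScheme({sid: codes[i] for i, sid in enumerate(sample_ids)})


# -------------------------------------------------------------- serialization
def coding_table(antigen_panel: AntigenPanel, scheme_a: CodingScheme,
                 scheme_b: CodingScheme | None = None) -> pd.DataFrame:
    """One record per antigen: id, peptide, category, config-A/B codes."""
    rows = []
    for e in antigen_panel.entries:
        rows.append({
            "antigen_id": e.antigen_id,
            "peptide": e.peptide,
            "category": e.category,
            "code_A": "+".join(scheme_a.code_map.get(e.antigen_id, ())),
            "code_B": "+".join(scheme_b.code_map.get(e.antigen_id, ())) if scheme_b else "",
        })
    return pd.DataFrame(rows)


def write_coding_table(path, antigen_panel: AntigenPanel, scheme_a: CodingScheme,
                       scheme_b: CodingScheme | None = None) -> None:
    coding_table(antigen_panel, scheme_a, scheme_b).to_csv(path, sep="\t", index=False)


def read_coding_table(path) -> tuple[AntigenPanel, CodingScheme, CodingScheme | None]:
    df = pd.read_csv(path, sep="\t").fillna("")
    antigen_panel = build_default_panel(df[["antigen_id", "peptide", "category"]])
    map_a = {r.antigen_id: tuple(r.code_A.split("+")) for r in df.itertuples() if r.code_A}
    scheme_a = CodingScheme("A", map_a)
    scheme_b = None
    if df["code_B"].astype(bool).any():
        map_b = {r.antigen_id: tuple(r.code_B.split("+")) for r in df.itertuples() if r.code_B}
        scheme_b = CodingScheme("B", map_b)
    return antigen_panel, scheme_a, scheme_b
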