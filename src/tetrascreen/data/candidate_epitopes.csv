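# candidate epitope fixture; predicted entries are deterministic placeholders (rng seed 20170915)
antigen_id,peptide,category
mLama4,VGFNFRTL,known
mAlg8,ITYTWTRL,known
cand01,PAMAFDLI,predicted
cand02,GNNSYEEM,predicted
cand03,WIIVFIDI,predicted
cand04,QKHWYKDL,predicted
cand05,FFMNYSYV,predicted
cand06,MTTLYPFM,predicted
cand07,DLWAFSKL,predicted
cand08,WLGYFRMM,predicted
cand09,CQFGYPLL,predicted
cand10,TFCTFIVM,predicted
cand11,SIHQYPPV,predicted
cand12,IHKIYPCI,predicted
cand13,YTFTYITI,predicted
cand14,IMAQFSMM,predicted
cand15,GYQNFWHV,predicted
cand16,WASCYHLV,predicted
cand17,VNIVYDGV,predicted
cand18,QASAFIAL,predicted
cand19,CCYNFIKM,predicted
cand20,MHRCYGYM,predicted
cand21,DSEKFNDM,predicted
cand22,DRYLFEGI,predicted
cand23,PMRDFALI,predicted
cand24,LHCRYDEL,predicted
cand25,VASMFRQM,predicted
cand26,WITDFKYI,predicted
cand27,IVCMYQEV,predicted
cand28,IILCFREM,predicted
cand29,AVDLFWDM,predicted
cand30,SIRNFMEM,predicted
cand31,WTSRFVWI,predicted
cand32,IWDFFTIV,predicted
cand33,VWFNFNGL,predicted
cand34,GFPDFRCM,predicted
cand35,YEKPFDTL,predicted
cand36,WQRRFEIV,predicted
cand37,NGIWYFPL,predicted
cand38,RAPGYYVL,predicted
cand39,EARVYGVV,predicted
cand40,MHCNYMVL,predicted
cand41,NRHAYSPM,predicted
cand42,GPFFFIGL,predicted
cand43,CEPGYFLV,predicted
cand44,MNYHFCQL,predicted
cand45,FCVGYMCV,predicted
cand46,HEWRFAIL,predicted
cand47,IGDPFKGL,predicted
cand48,SGSFYFNL,predicted
cand49,HVPTYFQL,predicted
cand50,SGDKFKGV,predicted
cand51,IAYMYSRV,predicted
cand52,PRVIYWAI,predicted
cand53,IRDWYWLI,predicted
cand54,KALWYQII,predicted
cand55,HFESYPLI,predicted
cand56,NNDAYTHI,predicted
cand57,MKPHFPSV,predicted
cand58,CQHSFPDI,predicted
cand59,GWYLFAFL,predicted
cand60,EWHDFWNV,predicted
cand61,SQEFYECL,predicted
cand62,FNNNYHML,predicted
cand63,PTYYFLAI,predicted
cand64,HWVYFTLL,predicted
cand65,CSKLFAQI,predicted
cand66,MEVNFQGI,predicted
cand67,FDTIYLLM,predicted
cand68,SLVFYDNM,predicted
cand69,SDDEFNIL,predicted
cand70,KQQSFSMM,predicted
cand71,NERHFALI,predicted
cand72,GAKHFCYL,predicted
cand73,PNHGYLKL,predicted
cand74,MPFRFYDV,predicted
cand75,NYPEFGSI,predicted
cand76,GRPVFTRM,predicted
cand77,GNGDYNNI,predicted
cand78,LKTSYQVM,predicted
cand79,KCAMYGVL,predicted
SIINFEKL,SIINFEKL,control
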