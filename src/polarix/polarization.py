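"""Filtering, derived/ancestral polarization and site classification.

A raw biallelic variant with an annotated ancestral allele is polarized
into a :class:`PolarizedSNP` carrying both the minor allele frequency
(MAF, always <= 0.5) and the derived allele frequency (DAF = frequency of
the allele absent from the ancestral state). The two agree when the minor
allele is derived and satisfy MAF = 1 - DAF when it is ancestral — the
identity behind the sign flip of any DAF-monotone score when correlated
against MAF on the two strata separately.

Site classes come from the transcript region (5'-UTR / CDS / 3'-UTR) and,
inside the CDS, from translating the reference and alternate codons
(synonymous / nonsynonymous / nonsense). Two regional flags mark the
translation-initiation-site window (the 50 nt of 5'-UTR immediately
upstream of the start codon) and splice-site margins (exonic positions
within 3 nt of an exon-exon junction).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_formats import RawSNPRecord, TranscriptModel
from .protein_consequence import translate_codon

__all__ = [
    "PolarizedSNP",
    "DAFBins",
    "DEFAULT_DAF_BINS",
    "filter_snps",
    "polarize",
    "assign_daf_bin",
    "classify_site",
    "polarize_cohort",
]

_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class DAFBins:
    """Eight DAF bins defined by 7 interior cut points.

    Bin k is the half-open interval (edge[k-1], edge[k]] with edge[0] = 0
    and edge[8] = 1. The defaults put bin 7 at (0.99, 0.999] and bin 8 at
    (0.999, 1).
    """

    edges: tuple[float, ...] = (0.001, 0.01, 0.1, 0.5, 0.9, 0.99, 0.999)

    def __post_init__(self) -> None:
        e = self.edges
        if len(e) != 7 or list(e) != sorted(set(e)) or not (0 < e[0] and e[-1] < 1):
            raise ValueError("need 7 strictly increasing interior edges in (0,1)")


DEFAULT_DAF_BINS = DAFBins()


@dataclass(frozen=True)
class PolarizedSNP:
    snp_id: str
    tx_id: str
    pos0: int
    ref: str
    alt: str
    ancestral: str
    derived: str
    maf: float
    daf: float
    minor_is_derived: bool
    site_class: str = ""
    in_tis: bool = False
    in_ss: bool = False
    daf_bin: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.daf < 1.0):
            raise ValueError(f"{self.snp_id}: daf must be in (0,1), got {self.daf}")
        if not (0.0 < self.maf <= 0.5):
            raise ValueError(f"{self.snp_id}: maf must be in (0,0.5], got {self.maf}")
        if self.derived == self.ancestral:
            raise ValueError(f"{self.snp_id}: derived equals ancestral allele")


# ---------------------------------------------------------------------------
# filtering


def filter_snps(
    records: Iterable[RawSNPRecord],
    transcripts: Mapping[str, TranscriptModel],
) -> tuple[list[RawSNPRecord], dict[str, int]]:
    """Apply the inclusion rules; every removal is logged by its first
    failing rule.

    Kept records are biallelic, have an ancestral allele matching ref or
    alt, a frequency strictly inside (0,1), and fall inside exactly one of
    the provided transcripts. Drop reasons, checked in order:
    ``multiallelic``, ``no_ancestral``, ``ancestral_mismatch``,
    ``no_frequency``, ``degenerate_frequency``, ``no_transcript``.
    """
    kept: list[RawSNPRecord] = []
    drop_log: Counter[str] = Counter()
    for rec in records:
        if len(rec.alts) != 1:
            drop_log["multiallelic"] += 1
            continue
        alt = rec.alts[0]
        if rec.ancestral is None:
            drop_log["no_ancestral"] += 1
            continue
        if rec.ancestral not in (rec.ref, alt):
            drop_log["ancestral_mismatch"] += 1
            continue
        if rec.alt_freq is None:
            drop_log["no_frequency"] += 1
            continue
        if not (0.0 < rec.alt_freq < 1.0):
            drop_log["degenerate_frequency"] += 1
            continue
        tx = transcripts.get(rec.chrom_or_tx_id)
        if tx is None or not (0 <= rec.pos - 1 < len(tx.seq)):
            drop_log["no_transcript"] += 1
            continue
        kept.append(rec)
    return kept, dict(drop_log)


# ---------------------------------------------------------------------------
# polarization


def polarize(record: RawSNPRecord) -> tuple[str, float, float, bool]:
    """(derived allele, daf, maf, minor_is_derived) for a filtered record.

    The VCF ALT frequency refers to the alternate allele; DAF is that
    frequency when ALT is derived and its complement when REF is derived.
    On the measure-zero tie daf == 0.5 the derived allele is counted as
    minor.
    """
    if len(record.alts) != 1 or record.ancestral not in (record.ref, record.alts[0]):
        raise ValueError(f"{record.snp_id}: record was not pre-filtered")
    if record.alt_freq is None or not (0.0 < record.alt_freq < 1.0):
        raise ValueError(f"{record.snp_id}: no usable frequency")
    alt = record.alts[0]
    derived = alt if record.ancestral == record.ref else record.ref
    daf = record.alt_freq if derived == alt else 1.0 - record.alt_freq
    maf = min(daf, 1.0 - daf)
    return derived, daf, maf, daf <= 0.5


def assign_daf_bin(daf: float, bins: DAFBins = DEFAULT_DAF_BINS) -> int:
    """The 1-based index of the half-open bin (edge[k-1], edge[k]] holding daf."""
    if not (0.0 < daf < 1.0):
        raise ValueError(f"daf must be in (0,1), got {daf}")
    for k, edge in enumerate(bins.edges, start=1):
        if daf <= edge:
            return k
    return 8


def classify_site(
    tx: TranscriptModel,
    pos0: int,
    ref: str,
    alt: str,
    tis_window: int = 50,
    ss_margin: int = 3,
) -> tuple[str, bool, bool]:
    """(site_class, in_tis, in_ss) for a substitution at ``pos0``.

    site_class is utr5/utr3 outside the CDS and syn/nonsyn/nonsense inside
    (nonsense covers any codon change that creates or destroys a stop).
    in_tis marks the ``tis_window`` nt of 5'-UTR immediately upstream of
    the start codon (truncated at the transcript start when the UTR is
    shorter). in_ss marks exonic positions within ``ss_margin`` nt of an
    exon-exon junction, on either side.
    """
    region = tx.region_of(pos0)
    cds_s, cds_e = tx.cds
    if region == "cds":
        codon_idx = (pos0 - cds_s) // 3
        within = (pos0 - cds_s) % 3
        codon = tx.seq[cds_s + 3 * codon_idx : cds_s + 3 * codon_idx + 3].upper()
        if codon[within] != ref.upper():
            raise ValueError(
                f"{tx.tx_id}:{pos0}: transcript base {codon[within]!r} != ref {ref!r}"
            )
        mut = codon[:within] + alt.upper() + codon[within + 1 :]
        aa_ref = translate_codon(codon)
        aa_alt = translate_codon(mut)
        if aa_ref == aa_alt:
            site_class = "syn"
        elif aa_ref == "*" or aa_alt == "*":
            site_class = "nonsense"
        else:
            site_class = "nonsyn"
    else:
        site_class = region

    in_tis = region == "utr5" and max(0, cds_s - tis_window) <= pos0 < cds_s
    # a junction at e separates bases e-1 | e; the exonic margin covers
    # the last ss_margin bases of the upstream exon and the first
    # ss_margin bases of the downstream exon
    in_ss = any(e - ss_margin <= pos0 <= e + ss_margin - 1 for e in tx.exon_ends)
    return site_class, in_tis, in_ss


# ---------------------------------------------------------------------------
# cohort-level driver


def polarize_cohort(
    records: Iterable[RawSNPRecord],
    transcripts: Mapping[str, TranscriptModel],
    bins: DAFBins = DEFAULT_DAF_BINS,
    tis_window: int = 50,
    ss_margin: int = 3,
) -> tuple[list[PolarizedSNP], dict[str, int]]:
    """Filter, polarize, classify and bin a raw cohort in one pass."""
    kept, drop_log = filter_snps(records, transcripts)
    out: list[PolarizedSNP] = []
    for rec in kept:
        derived, daf, maf, minor_is_derived = polarize(rec)
        tx = transcripts[rec.chrom_or_tx_id]
        pos0 = rec.pos - 1  # the single 1-based -> 0-based conversion
        site_class, in_tis, in_ss = classify_site(
            tx, pos0, rec.ref, rec.alts[0], tis_window, ss_margin
        )
        out.append(
            PolarizedSNP(
                snp_id=rec.snp_id,
                tx_id=rec.chrom_or_tx_id,
                pos0=pos0,
                ref=rec.ref,
                alt=rec.alts[0],
                ancestral=rec.ancestral,
                derived=derived,
                maf=maf,
                daf=daf,
                minor_is_derived=minor_is_derived,
                site_class=site_class,
                in_tis=in_tis,
                in_ss=in_ss,
                daf_bin=assign_daf_bin(daf, bins),
            )
        )
    return out, drop_log


def cohort_frame(snps: Sequence[PolarizedSNP]) -> pd.DataFrame:
    """Long-format table of a polarized cohort (one row per kept SNP)."""
    cols = [
        "snp_id",
        "tx_id",
        "pos0",
        "ref",
        "alt",
        "ancestral",
        "derived",
        "maf",
        "daf",
        "minor_is_derived",
        "site_class",
        "in_tis",
        "in_ss",
        "daf_bin",
    ]
    return pd.DataFrame([{c: getattr(s, c) for c in cols} for s in snps], columns=cols)
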