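"""Readers and writers for the external formats the pipeline consumes.

All coordinates are 0-based half-open *inside* the package. The single
exception is :class:`RawSNPRecord`, which keeps the 1-based VCF position so
that the 1-based -> 0-based conversion happens exactly once, in the
polarization stage that consumes these records.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import pysam
import yaml

__all__ = [
    "RawSNPRecord",
    "TranscriptModel",
    "GeneAnnotation",
    "SNPAnnotation",
    "PipelineConfig",
    "VCFParseError",
    "ValidationError",
    "read_vcf",
    "read_transcripts",
    "read_gene_annotations",
    "read_snp_annotations",
    "write_report",
]

_BASES = frozenset("ACGT")


class VCFParseError(ValueError):
    """Raised when a VCF file cannot be parsed."""


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


@dataclass(frozen=True)
class RawSNPRecord:
    """One VCF row, unfiltered; position is 1-based per VCF convention."""

    chrom_or_tx_id: str
    pos: int
    snp_id: str
    ref: str
    alts: tuple[str, ...]
    ancestral: str | None = None
    alt_freq: float | None = None
    info: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"VCF position must be >= 1, got {self.pos}")
        if self.alt_freq is not None and not (0.0 <= self.alt_freq <= 1.0):
            raise ValidationError(f"alt_freq outside [0,1]: {self.alt_freq}")


@dataclass(frozen=True)
class TranscriptModel:
    """A sense-strand transcript with UTR/CDS structure.

    ``utr5``, ``cds`` and ``utr3`` are half-open intervals in 0-based
    transcript coordinates that tile ``[0, len(seq))``. ``exon_ends`` lists
    the transcript positions immediately *after* an exon-exon junction
    (i.e. the first base of the downstream exon).
    """

    tx_id: str
    gene_id: str
    seq: str
    utr5: tuple[int, int]
    cds: tuple[int, int]
    utr3: tuple[int, int]
    exon_ends: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        n = len(self.seq)
        u5, c, u3 = self.utr5, self.cds, self.utr3
        if u5[0] != 0 or u5[1] != c[0] or c[1] != u3[0] or u3[1] != n:
            raise ValidationError(
                f"{self.tx_id}: regions {u5},{c},{u3} do not tile [0,{n})"
            )
        if (c[1] - c[0]) % 3 != 0:
            raise ValidationError(
                f"{self.tx_id}: CDS length {c[1] - c[0]} not divisible by 3"
            )
        if any(not (0 < e < n) for e in self.exon_ends):
            raise ValidationError(f"{self.tx_id}: exon junction outside transcript")
        if list(self.exon_ends) != sorted(set(self.exon_ends)):
            raise ValidationError(f"{self.tx_id}: exon_ends not sorted/unique")

    def region_of(self, pos0: int) -> str:
        if not 0 <= pos0 < len(self.seq):
            raise ValidationError(f"{self.tx_id}: position {pos0} outside transcript")
        if pos0 < self.cds[0]:
            return "utr5"
        if pos0 < self.cds[1]:
            return "cds"
        return "utr3"


@dataclass(frozen=True)
class GeneAnnotation:
    gene_id: str
    omega_mouse: float | None = None
    omega_chimp: float | None = None
    essential: bool = False
    mendelian: bool = False

    def __post_init__(self) -> None:
        for w in (self.omega_mouse, self.omega_chimp):
            if w is not None and w < 0:
                raise ValidationError(f"{self.gene_id}: omega must be >= 0")


@dataclass(frozen=True)
class SNPAnnotation:
    snp_id: str
    conservation_scores: Mapping[str, float] = field(default_factory=dict)
    age_ky: float | None = None

    def __post_init__(self) -> None:
        if self.age_ky is not None and self.age_ky < 0:
            raise ValidationError(f"{self.snp_id}: age must be >= 0 kiloyears")


@dataclass
class PipelineConfig:
    """Run-level knobs; defaults follow the analysis' stated conditions."""

    seed: int = 0
    window_nt: int = 150
    # interior cut points of the 8 DAF bins (bin k = (edge[k-1], edge[k]])
    daf_bin_edges: tuple[float, ...] = (0.001, 0.01, 0.1, 0.5, 0.9, 0.99, 0.999)
    rare_maf: float = 0.01
    tis_window_nt: int = 50
    ss_margin_nt: int = 3
    age_young_ky: float = 300.0
    age_old_ky: float = 700.0
    daf_high: float = 0.8
    daf_low: float = 0.2
    expression_quantile: float = 0.2
    expression_offset: float = 1.0
    ts_tv_targets: dict = field(
        default_factory=lambda: {"utr5": 2.0, "cds": 2.0, "utr3": 2.0}
    )
    pair_energies: dict = field(
        default_factory=lambda: {"GC": -3.0, "AU": -2.0, "GU": -1.0}
    )
    noncanonical_energy: float = 8.0
    min_loop: int = 3
    beta: float = 1.0
    log_odds_scale: bool = False

    def __post_init__(self) -> None:
        edges = tuple(self.daf_bin_edges)
        if any(not (0.0 < e < 1.0) for e in edges) or list(edges) != sorted(edges):
            raise ValidationError("daf_bin_edges must be strictly increasing in (0,1)")
        if len(set(edges)) != len(edges):
            raise ValidationError("daf_bin_edges must be distinct")
        if self.window_nt < 11:
            raise ValidationError("window_nt must be >= 11")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.pop("_comment", None)
        if "daf_bin_edges" in data:
            data["daf_bin_edges"] = tuple(data["daf_bin_edges"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["daf_bin_edges"] = list(data["daf_bin_edges"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# readers


def read_vcf(path: str | Path) -> list[RawSNPRecord]:
    """Read a VCF 4.x file into raw, unfiltered SNP records.

    The ancestral allele is taken from INFO ``AA=`` (1000 Genomes dialect;
    lower-case low-confidence calls are upper-cased) and the global derived
    allele frequency from INFO ``AF=``. Multi-allelic rows are preserved;
    filtering is the polarization stage's job.
    """
    path = Path(path)
    try:
        vf = pysam.VariantFile(str(path))
    except Exception as exc:  # pragma: no cover - pysam error classes vary
        raise VCFParseError(f"{path}: not a readable VCF ({exc})") from exc
    records: list[RawSNPRecord] = []
    with vf:
        for lineno, rec in enumerate(vf.fetch() if vf.index else vf, start=1):
            try:
                alts = tuple(a for a in (rec.alts or ()))
                aa = rec.info.get("AA")
                if isinstance(aa, tuple):
                    aa = aa[0]
                ancestral = str(aa).upper() if aa not in (None, ".", "") else None
                af = rec.info.get("AF")
                if isinstance(af, tuple):
                    af = af[0]
                alt_freq = float(af) if af is not None else None
                info = {k: str(v) for k, v in rec.info.items()}
                records.append(
                    RawSNPRecord(
                        chrom_or_tx_id=rec.chrom,
                        pos=rec.pos,
                        snp_id=rec.id or f"{rec.chrom}:{rec.pos}",
                        ref=rec.ref,
                        alts=alts,
                        ancestral=ancestral,
                        alt_freq=alt_freq,
                        info=info,
                    )
                )
            except (ValueError, TypeError) as exc:
                raise VCFParseError(f"{path}: malformed record #{lineno}: {exc}") from exc
    return records


_REGION_COLS = [
    "tx_id",
    "gene_id",
    "utr5_start",
    "utr5_end",
    "cds_start",
    "cds_end",
    "utr3_start",
    "utr3_end",
    "exon_ends",
]


def read_transcripts(
    fasta_path: str | Path, regions_path: str | Path
) -> dict[str, TranscriptModel]:
    """Load sense-strand transcript sequences plus their region annotation.

    The regions file is a TSV with columns ``tx_id gene_id utr5_start
    utr5_end cds_start cds_end utr3_start utr3_end exon_ends`` (intervals
    0-based half-open, ``exon_ends`` a comma list, possibly empty).
    """
    from Bio import SeqIO

    seqs = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(fasta_path), "fasta")}
    table = pd.read_csv(regions_path, sep="\t", dtype={"exon_ends": str})
    missing = [c for c in _REGION_COLS if c not in table.columns]
    if missing:
        raise ValidationError(f"{regions_path}: missing columns {missing}")
    out: dict[str, TranscriptModel] = {}
    for row in table.itertuples(index=False):
        if row.tx_id not in seqs:
            raise ValidationError(f"{row.tx_id}: no FASTA sequence for region row")
        raw = row.exon_ends
        ends: tuple[int, ...]
        if raw is None or (isinstance(raw, float) and pd.isna(raw)) or raw in ("", "."):
            ends = ()
        else:
            ends = tuple(int(x) for x in str(raw).split(",") if x != "")
        out[row.tx_id] = TranscriptModel(
            tx_id=row.tx_id,
            gene_id=row.gene_id,
            seq=seqs[row.tx_id],
            utr5=(int(row.utr5_start), int(row.utr5_end)),
            cds=(int(row.cds_start), int(row.cds_end)),
            utr3=(int(row.utr3_start), int(row.utr3_end)),
            exon_ends=ends,
        )
    return out


def read_gene_annotations(path: str | Path) -> dict[str, GeneAnnotation]:
    df = pd.read_csv(path, sep="\t")
    out = {}
    for row in df.itertuples(index=False):
        out[row.gene_id] = GeneAnnotation(
            gene_id=row.gene_id,
            omega_mouse=None if pd.isna(row.omega_mouse) else float(row.omega_mouse),
            omega_chimp=None if pd.isna(row.omega_chimp) else float(row.omega_chimp),
            essential=bool(row.essential),
            mendelian=bool(row.mendelian),
        )
    return out


def read_snp_annotations(path: str | Path) -> dict[str, SNPAnnotation]:
    df = pd.read_csv(path, sep="\t")
    score_cols = [c for c in df.columns if c not in ("snp_id", "age_ky")]
    out = {}
    for row in df.itertuples(index=False):
        scores = {
            c: float(getattr(row, c))
            for c in score_cols
            if not pd.isna(getattr(row, c))
        }
        age = getattr(row, "age_ky", None)
        out[row.snp_id] = SNPAnnotation(
            snp_id=row.snp_id,
            conservation_scores=scores,
            age_ky=None if age is None or pd.isna(age) else float(age),
        )
    return out


# ---------------------------------------------------------------------------
# report writer


def write_report(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    config: PipelineConfig | None = None,
    seed: int | None = None,
) -> list[Path]:
    """Write one TSV per result table plus a run manifest.

    Output is deterministic: column order is taken from each table as-is,
    rows are written in table order, and floats use a fixed '%.10g' format,
    so two runs from the same config and seed are byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name in sorted(tables):
        dest = out_dir / f"{name}.tsv"
        tables[name].to_csv(dest, sep="\t", index=False, float_format="%.10g")
        written.append(dest)
    manifest = {
        "tables": [p.name for p in written],
        "seed": seed,
        "config": dataclasses.asdict(config) if config is not None else None,
    }
    mpath = out_dir / "run_manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=list) + "\n")
    written.append(mpath)
    return written
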