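"""Synthetic transcriptomes, expression tables and SNP cohorts with planted
population-genetic structure.

The simulator encodes, as ground truth, the relationships the analysis is
built to detect:

* each SNP carries a scalar deleteriousness effect ``x ~ Exponential(1)``
  and its derived allele frequency is drawn ``DAF ~ Beta(a0, a0 + s*x)``,
  so larger effects are pushed toward low frequency (purifying-selection
  shape) and ``s`` is the single knob coupling effect and frequency;
* a conservation-like score decreases linearly in DAF with Gaussian noise,
  which forces the minor-allele sign flip: on the derived-minor stratum
  MAF = DAF so score and MAF are negatively correlated, while on the
  ancestral-minor stratum MAF = 1 - DAF and the correlation reverses;
* allele age grows linearly with DAF, with a small injected fraction of
  "quick-running" (young, high-DAF) and "slow-running" (old, low-DAF)
  outliers labelled in the truth record;
* synonymous codon choice is biased toward a designated optimal codon with
  probability logistic in expression, planting the usage signal the codon
  optimality odds ratio recovers;
* essential/Mendelian genes and TIS/SS positions multiply ``s``, lowering
  DAF in those strata.

ALT is always the derived allele in the emitted VCF; ancestral-minor cases
arise purely from DAF > 0.5, so the polarization stage (not the simulator)
is responsible for the strata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import RawSNPRecord, TranscriptModel
from .protein_consequence import (
    AMINO_ACIDS,
    GENETIC_CODE,
    SYNONYMOUS_FAMILY,
    translate_codon,
)

__all__ = [
    "SyntheticTruth",
    "simulate_transcriptome",
    "draw_optimal_codons",
    "simulate_expression",
    "simulate_snps",
    "simulate_gene_annotations",
    "write_vcf",
    "write_fasta",
    "write_regions",
    "write_snp_annotations_table",
]

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_BASES = "ACGT"
# GC-preserving third-base edits that break an in-frame stop codon
_STOP_FIX = {"TAA": "TAT", "TAG": "TAC", "TGA": "TGT"}


@dataclass
class SyntheticTruth:
    """Planted parameters; the reference against which recovery is tested."""

    effect_by_snp: dict[str, float] = field(default_factory=dict)
    daf_model_params: tuple[float, float] = (0.25, 2.0)  # (alpha0, s)
    optimal_codons: dict[str, str] = field(default_factory=dict)
    corner_labels: dict[str, str] = field(default_factory=dict)
    score_noise_sd: float = 1.0
    score_slope: float = 3.0
    score_intercept: float = 5.0
    age_model_params: tuple[float, float] = (1.0, 100.0)  # (ky per DAF*1000, sd)
    gene_s_multiplier: dict[str, float] = field(default_factory=dict)
    tis_multiplier: float = 1.0
    ss_multiplier: float = 1.0

    def to_json(self, path: str | Path) -> None:
        data = {
            "effect_by_snp": self.effect_by_snp,
            "daf_model_params": list(self.daf_model_params),
            "optimal_codons": self.optimal_codons,
            "corner_labels": self.corner_labels,
            "score_noise_sd": self.score_noise_sd,
            "score_slope": self.score_slope,
            "score_intercept": self.score_intercept,
            "age_model_params": list(self.age_model_params),
            "gene_s_multiplier": self.gene_s_multiplier,
            "tis_multiplier": self.tis_multiplier,
            "ss_multiplier": self.ss_multiplier,
        }
        Path(path).write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# transcriptome


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list(_BASES))[rng.choice(4, size=n, p=p)])


def simulate_transcriptome(
    n_genes: int,
    mean_utr5: int = 120,
    mean_cds_codons: int = 300,
    mean_utr3: int = 300,
    gc: float = 0.5,
    seed: int = 0,
) -> dict[str, TranscriptModel]:
    """One transcript per gene with UTR/CDS structure and exon junctions.

    The CDS begins with ATG, ends with a stop and contains no internal
    stops: any in-frame stop arising from the iid base draw is repaired by
    a GC-preserving third-base edit, so the expected GC content stays at
    ``gc`` apart from the six fixed start/stop bases. 1-4 exon junctions
    are placed uniformly per transcript.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if not 0.0 < gc < 1.0:
        raise ValueError("gc must be in (0,1)")
    if min(mean_utr5, mean_cds_codons, mean_utr3) <= 0:
        raise ValueError("mean lengths must be positive")
    rng = np.random.default_rng(seed)
    out: dict[str, TranscriptModel] = {}
    stops = ("TAA", "TAG", "TGA")
    for g in range(n_genes):
        u5 = max(10, int(rng.poisson(mean_utr5)))
        n_codons = max(3, int(rng.poisson(mean_cds_codons)))
        u3 = max(10, int(rng.poisson(mean_utr3)))
        utr5 = _random_bases(rng, u5, gc)
        interior = _random_bases(rng, 3 * (n_codons - 2), gc)
        codons = [interior[i : i + 3] for i in range(0, len(interior), 3)]
        codons = [_STOP_FIX.get(c, c) for c in codons]
        cds = "ATG" + "".join(codons) + stops[rng.integers(3)]
        utr3 = _random_bases(rng, u3, gc)
        seq = utr5 + cds + utr3
        L = len(seq)
        n_j = int(rng.integers(1, 5))
        ends = tuple(sorted(set(int(e) for e in rng.integers(1, L, size=n_j))))
        tx_id, gene_id = f"tx{g:05d}", f"g{g:05d}"
        out[tx_id] = TranscriptModel(
            tx_id=tx_id,
            gene_id=gene_id,
            seq=seq,
            utr5=(0, u5),
            cds=(u5, u5 + len(cds)),
            utr3=(u5 + len(cds), L),
            exon_ends=ends,
        )
    return out


# ---------------------------------------------------------------------------
# expression and codon bias


def draw_optimal_codons(seed: int = 0) -> dict[str, str]:
    """Designate one optimal codon per multi-codon synonymous family."""
    rng = np.random.default_rng(seed)
    out = {}
    for aa in AMINO_ACIDS:
        fam = SYNONYMOUS_FAMILY[aa]
        out[aa] = fam[int(rng.integers(len(fam)))]
    return out


def simulate_expression(
    transcripts: Mapping[str, TranscriptModel],
    optimal_codons: Mapping[str, str],
    bias_strength: float = 2.0,
    n_tissues: int = 8,
    seed: int = 0,
    tissue_noise_sd: float = 0.5,
) -> tuple[pd.DataFrame, dict[str, TranscriptModel]]:
    """Latent expression per gene plus expression-dependent codon rewriting.

    Each gene gets a latent level ``exp(1.5 + 1.2 z)`` with ``z ~ N(0,1)``;
    tissue columns multiply it by lognormal noise. Within each synonymous
    family of size k the optimal codon is used with probability
    ``logistic(bias_strength * z + logit(1/k))`` (uniform within the family
    at bias 0) and the remaining codons share the rest uniformly. Returns
    the gene-by-tissue table and the rewritten transcriptome.
    """
    if bias_strength < 0:
        raise ValueError("bias_strength must be >= 0")
    if n_tissues < 1:
        raise ValueError("n_tissues must be >= 1")
    rng = np.random.default_rng(seed)
    tx_ids = sorted(transcripts)
    z = rng.normal(size=len(tx_ids))
    levels = np.exp(1.5 + 1.2 * z)
    noise = np.exp(rng.normal(0.0, tissue_noise_sd, size=(len(tx_ids), n_tissues)))
    genes = [transcripts[t].gene_id for t in tx_ids]
    table = pd.DataFrame(
        levels[:, None] * noise,
        index=pd.Index(genes, name="gene_id"),
        columns=[f"tissue_{k}" for k in range(n_tissues)],
    )

    rewritten: dict[str, TranscriptModel] = {}
    for zi, tx_id in zip(z, tx_ids):
        tx = transcripts[tx_id]
        s, e = tx.cds
        cds = tx.seq[s:e]
        new: list[str] = []
        for i in range(0, len(cds), 3):
            codon = cds[i : i + 3]
            aa = translate_codon(codon)
            fam = SYNONYMOUS_FAMILY.get(aa, (codon,))
            if aa == "*" or len(fam) == 1 or i == 0:
                new.append(codon)
                continue
            k = len(fam)
            opt = optimal_codons.get(aa, fam[0])
            logit0 = np.log((1.0 / k) / (1.0 - 1.0 / k))
            p_opt = 1.0 / (1.0 + np.exp(-(bias_strength * zi + logit0)))
            if rng.random() < p_opt:
                new.append(opt)
            else:
                others = [c for c in fam if c != opt]
                new.append(others[int(rng.integers(len(others)))])
        new_seq = tx.seq[:s] + "".join(new) + tx.seq[e:]
        rewritten[tx_id] = TranscriptModel(
            tx_id=tx.tx_id,
            gene_id=tx.gene_id,
            seq=new_seq,
            utr5=tx.utr5,
            cds=tx.cds,
            utr3=tx.utr3,
            exon_ends=tx.exon_ends,
        )
    return table, rewritten


# ---------------------------------------------------------------------------
# gene annotations


def simulate_gene_annotations(
    transcripts: Mapping[str, TranscriptModel],
    seed: int = 0,
    essential_fraction: float = 0.1,
    mendelian_fraction: float = 0.3,
    penalty: float = 2.0,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-gene omega, essential and Mendelian flags, plus s-multipliers.

    omega ~ lognormal (median ~0.15, typical of mammalian purifying
    selection); each flag independently multiplies the gene's selection
    knob ``s`` by ``penalty`` (penalty 1 = no planted category effect).
    Returns the annotation table and the per-gene multiplier map recorded
    in SyntheticTruth.
    """
    if not transcripts:
        raise ValueError("transcripts must be nonempty")
    rng = np.random.default_rng(seed)
    genes = sorted({tx.gene_id for tx in transcripts.values()})
    omega_m = np.exp(rng.normal(np.log(0.15), 0.8, size=len(genes)))
    omega_c = omega_m * np.exp(rng.normal(0.0, 0.3, size=len(genes)))
    essential = rng.random(len(genes)) < essential_fraction
    mendelian = rng.random(len(genes)) < mendelian_fraction
    table = pd.DataFrame(
        {
            "gene_id": genes,
            "omega_mouse": omega_m,
            "omega_chimp": omega_c,
            "essential": essential,
            "mendelian": mendelian,
        }
    )
    mult = {
        g: (penalty if e else 1.0) * (penalty if m else 1.0)
        for g, e, m in zip(genes, essential, mendelian)
    }
    return table, mult


# ---------------------------------------------------------------------------
# SNP cohort


def simulate_snps(
    transcripts: Mapping[str, TranscriptModel],
    n_snps: int,
    daf_params: tuple[float, float] = (0.25, 2.0),
    corner_fraction: float = 0.0,
    seed: int = 0,
    score_intercept: float = 5.0,
    score_slope: float = 3.0,
    score_noise_sd: float = 1.0,
    age_per_daf_ky: float = 1.0,
    age_noise_sd_ky: float = 100.0,
    gene_s_multiplier: Mapping[str, float] | None = None,
    tis_multiplier: float = 1.0,
    ss_multiplier: float = 1.0,
    tis_window: int = 50,
    ss_margin: int = 3,
) -> tuple[list[RawSNPRecord], pd.DataFrame, SyntheticTruth]:
    """Sample a SNP cohort with the planted effect-frequency coupling.

    Sites are uniform over the concatenated transcripts; the ancestral
    allele is the transcript (reference) base and the derived allele is a
    transition with probability 2/3, else one of the two transversions.
    Effects ``x ~ Exp(1)``; ``DAF ~ Beta(a0, a0 + s_eff * x)`` where
    ``s_eff`` multiplies in any gene-category and TIS/SS penalties. The
    emitted VCF-style records carry ALT = derived and AF = DAF.
    ``corner_fraction`` of SNPs are overwritten as quick-running
    (age ~ U(50,300) ky, DAF ~ U(0.8,1)) or slow-running (age ~ U(700,1200),
    DAF ~ U(0,0.2)) and labelled in the truth record.
    """
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    alpha0, s = daf_params
    if alpha0 <= 0 or s < 0:
        raise ValueError("daf_params require alpha0 > 0 and s >= 0")
    if not 0.0 <= corner_fraction <= 0.05:
        raise ValueError("corner_fraction must be in [0, 0.05]")
    rng = np.random.default_rng(seed)
    tx_ids = sorted(transcripts)
    lengths = np.array([len(transcripts[t].seq) for t in tx_ids])
    cum = np.cumsum(lengths)
    total = int(cum[-1])

    sites = rng.integers(0, total, size=n_snps)
    tx_idx = np.searchsorted(cum, sites, side="right")
    pos0 = sites - np.concatenate(([0], cum[:-1]))[tx_idx]

    x = rng.exponential(1.0, size=n_snps)
    is_ts = rng.random(n_snps) < (2.0 / 3.0)

    records: list[RawSNPRecord] = []
    truth = SyntheticTruth(
        daf_model_params=(alpha0, s),
        score_noise_sd=score_noise_sd,
        score_slope=score_slope,
        score_intercept=score_intercept,
        age_model_params=(age_per_daf_ky, age_noise_sd_ky),
        gene_s_multiplier=dict(gene_s_multiplier or {}),
        tis_multiplier=tis_multiplier,
        ss_multiplier=ss_multiplier,
    )

    s_eff = np.full(n_snps, s)
    refs: list[str] = []
    deriveds: list[str] = []
    for i in range(n_snps):
        tx = transcripts[tx_ids[tx_idx[i]]]
        p = int(pos0[i])
        ref = tx.seq[p].upper()
        refs.append(ref)
        if is_ts[i]:
            deriveds.append(_TRANSITION[ref])
        else:
            tv = [b for b in _BASES if b != ref and b != _TRANSITION[ref]]
            deriveds.append(tv[int(rng.integers(2))])
        if gene_s_multiplier:
            s_eff[i] *= gene_s_multiplier.get(tx.gene_id, 1.0)
        cds_s = tx.cds[0]
        if max(0, cds_s - tis_window) <= p < cds_s:
            s_eff[i] *= tis_multiplier
        if any(e - ss_margin <= p <= e + ss_margin - 1 for e in tx.exon_ends):
            s_eff[i] *= ss_multiplier

    daf = rng.beta(alpha0, alpha0 + s_eff * x)
    daf = np.clip(daf, 1e-6, 1.0 - 1e-6)

    labels = np.array(["none"] * n_snps, dtype=object)
    n_corner = int(np.floor(corner_fraction * n_snps))
    if n_corner:
        chosen = rng.choice(n_snps, size=n_corner, replace=False)
        half = n_corner // 2
        for j, idx in enumerate(chosen):
            if j < half or (n_corner % 2 and j == n_corner - 1 and rng.random() < 0.5):
                labels[idx] = "quick"
            else:
                labels[idx] = "slow"
        # resolve the odd leftover deterministically from the draw above
        for idx in chosen:
            if labels[idx] == "quick":
                daf[idx] = rng.uniform(0.8, 1.0 - 1e-6)
            else:
                daf[idx] = rng.uniform(1e-6, 0.2)

    score = score_intercept - score_slope * daf + rng.normal(
        0.0, score_noise_sd, size=n_snps
    )
    age = age_per_daf_ky * daf * 1000.0 + rng.normal(0.0, age_noise_sd_ky, size=n_snps)
    age = np.maximum(age, 0.0)
    for i in range(n_snps):
        if labels[i] == "quick":
            age[i] = rng.uniform(50.0, 300.0)
        elif labels[i] == "slow":
            age[i] = rng.uniform(700.0, 1200.0)

    snp_ids = [f"snp{i:06d}" for i in range(n_snps)]
    for i in range(n_snps):
        records.append(
            RawSNPRecord(
                chrom_or_tx_id=tx_ids[tx_idx[i]],
                pos=int(pos0[i]) + 1,
                snp_id=snp_ids[i],
                ref=refs[i],
                alts=(deriveds[i],),
                ancestral=refs[i],
                alt_freq=float(daf[i]),
            )
        )
        truth.effect_by_snp[snp_ids[i]] = float(x[i])
        truth.corner_labels[snp_ids[i]] = str(labels[i])

    annotations = pd.DataFrame(
        {"snp_id": snp_ids, "cons_score": score, "age_ky": age}
    )
    return records, annotations, truth


# ---------------------------------------------------------------------------
# writers (same dialects io_formats reads)


def write_vcf(records: Sequence[RawSNPRecord], path: str | Path) -> None:
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">',
        '##INFO=<ID=AF,Number=A,Type=Float,Description="Derived (ALT) allele frequency">',
    ]
    for chrom in sorted({r.chrom_or_tx_id for r in records}):
        lines.append(f"##contig=<ID={chrom}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for r in sorted(records, key=lambda r: (r.chrom_or_tx_id, r.pos, r.snp_id)):
        info = []
        if r.ancestral is not None:
            info.append(f"AA={r.ancestral}")
        if r.alt_freq is not None:
            info.append(f"AF={r.alt_freq:.8g}")
        lines.append(
            f"{r.chrom_or_tx_id}\t{r.pos}\t{r.snp_id}\t{r.ref}\t"
            f"{','.join(r.alts)}\t.\t.\t{';'.join(info) or '.'}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_fasta(transcripts: Mapping[str, TranscriptModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for tx_id in sorted(transcripts):
            seq = transcripts[tx_id].seq
            fh.write(f">{tx_id}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_regions(transcripts: Mapping[str, TranscriptModel], path: str | Path) -> None:
    rows = []
    for tx_id in sorted(transcripts):
        tx = transcripts[tx_id]
        rows.append(
            {
                "tx_id": tx.tx_id,
                "gene_id": tx.gene_id,
                "utr5_start": tx.utr5[0],
                "utr5_end": tx.utr5[1],
                "cds_start": tx.cds[0],
                "cds_end": tx.cds[1],
                "utr3_start": tx.utr3[0],
                "utr3_end": tx.utr3[1],
                "exon_ends": ",".join(str(e) for e in tx.exon_ends),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_snp_annotations_table(annotations: pd.DataFrame, path: str | Path) -> None:
    annotations.to_csv(path, sep="\t", index=False, float_format="%.8g")
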