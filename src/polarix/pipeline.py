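"""End-to-end orchestration: polarize a raw cohort, attach annotations and
compute per-variant consequence metrics with a single shared code path for
observed SNPs and background mutations."""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import rna_ensemble
from .io_formats import PipelineConfig, RawSNPRecord, TranscriptModel
from .polarization import DAFBins, PolarizedSNP, cohort_frame, polarize_cohort
from .protein_consequence import (
    CodonOptimalityTable,
    blosum62_score,
    delta_codon_optimality,
    grantham_distance,
    hydrophobicity_delta,
    translate_codon,
)

__all__ = ["score_cohort", "score_variant_table", "attach_annotations"]


def _codon_pair(tx: TranscriptModel, pos0: int, ref: str, alt: str) -> tuple[str, str]:
    s = tx.cds[0]
    idx = (pos0 - s) // 3
    within = (pos0 - s) % 3
    codon = tx.seq[s + 3 * idx : s + 3 * idx + 3].upper()
    mut = codon[:within] + alt.upper() + codon[within + 1 :]
    return codon, mut


def score_variant_table(
    table: pd.DataFrame,
    transcripts: Mapping[str, TranscriptModel],
    optimality: CodonOptimalityTable | None = None,
    config: PipelineConfig | None = None,
    structural: bool = False,
) -> pd.DataFrame:
    """Add consequence metrics to any table with tx_id/pos0/ref/alt/site_class.

    Protein metrics are computed for nonsynonymous rows (nonsense excluded:
    amino-acid matrices are undefined for stops), |dO_codon| for synonymous
    rows, and (optionally, it is the expensive step) the three structural
    metrics for every row. Works identically for SNP and background tables.
    """
    config = config or PipelineConfig()
    out = table.copy()
    n = len(out)
    gr = np.full(n, np.nan)
    dh = np.full(n, np.nan)
    bl = np.full(n, np.nan)
    do = np.full(n, np.nan)
    for i, row in enumerate(out.itertuples(index=False)):
        tx = transcripts[row.tx_id]
        if row.site_class == "nonsyn":
            cw, cm = _codon_pair(tx, row.pos0, row.ref, row.alt)
            aw, am = translate_codon(cw), translate_codon(cm)
            gr[i] = grantham_distance(aw, am)
            dh[i] = hydrophobicity_delta(aw, am)
            bl[i] = blosum62_score(aw, am)
        elif row.site_class == "syn" and optimality is not None:
            cw, cm = _codon_pair(tx, row.pos0, row.ref, row.alt)
            do[i] = delta_codon_optimality(
                cw, cm, optimality, log_scale=config.log_odds_scale
            )
    out["grantham"] = gr
    out["hydrophobicity_delta"] = dh
    out["blosum62"] = bl
    out["delta_codon_optimality"] = do

    if structural:
        model = rna_ensemble.EnergyModel(
            pair_energy=dict(config.pair_energies),
            noncanonical_energy=config.noncanonical_energy,
            min_loop=config.min_loop,
            beta=config.beta,
        )
        d = np.full(n, np.nan)
        g = np.full(n, np.nan)
        bd = np.full(n, np.nan)
        for i, row in enumerate(out.itertuples(index=False)):
            eff = rna_ensemble.score_structural_effect(
                transcripts[row.tx_id], row.pos0, row.ref, row.alt,
                model=model, width=config.window_nt,
            )
            d[i] = eff.relative_entropy
            g[i] = eff.mfe_gap
            bd[i] = eff.bpp_distance
        out["rel_entropy"] = d
        out["mfe_gap"] = g
        out["bpp_distance"] = bd
    return out


def attach_annotations(
    cohort: pd.DataFrame,
    transcripts: Mapping[str, TranscriptModel],
    snp_annotations: pd.DataFrame | None = None,
    gene_annotations: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Join per-SNP scores/ages and per-gene omega/category flags."""
    out = cohort.copy()
    out["gene_id"] = [transcripts[t].gene_id for t in out["tx_id"]]
    if snp_annotations is not None:
        ann = snp_annotations.rename(
            columns={
                c: (c if c in ("snp_id", "age_ky") else f"score_{c}")
                for c in snp_annotations.columns
                if not c.startswith("score_")
            }
        )
        out = out.merge(ann, on="snp_id", how="left")
    if gene_annotations is not None:
        out = out.merge(gene_annotations, on="gene_id", how="left")
    return out


def score_cohort(
    records: Iterable[RawSNPRecord],
    transcripts: Mapping[str, TranscriptModel],
    optimality: CodonOptimalityTable | None = None,
    snp_annotations: pd.DataFrame | None = None,
    gene_annotations: pd.DataFrame | None = None,
    config: PipelineConfig | None = None,
    structural: bool = False,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Raw VCF records -> filtered, polarized, annotated, scored table."""
    config = config or PipelineConfig()
    bins = DAFBins(edges=tuple(config.daf_bin_edges))
    snps, drop_log = polarize_cohort(
        records, transcripts, bins, config.tis_window_nt, config.ss_margin_nt
    )
    frame = cohort_frame(snps)
    if frame.empty:
        return frame, drop_log
    frame = attach_annotations(frame, transcripts, snp_annotations, gene_annotations)
    frame = score_variant_table(frame, transcripts, optimality, config, structural)
    return frame, drop_log
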