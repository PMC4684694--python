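"""Protein- and translation-level consequences of coding substitutions.

Nonsynonymous changes are scored with three classical substitution metrics
(Grantham chemical distance, absolute change in the Argos membrane
hydrophobicity index, BLOSUM62 log-odds). Synonymous changes are scored by
the change in codon optimality |dO_codon|, where a codon's optimality O_c
is the odds ratio of its usage within its synonymous family between the
top-20% and bottom-20% expressed genes (expression summarized per gene as
the geometric mean across tissues).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .io_formats import TranscriptModel

__all__ = [
    "SubstitutionMatrices",
    "CodonOptimalityTable",
    "load_substitution_matrices",
    "grantham_distance",
    "hydrophobicity_delta",
    "blosum62_score",
    "translate_codon",
    "compute_codon_optimality",
    "delta_codon_optimality",
]

AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")

_FIXTURE_SHA256 = {
    "grantham.tsv": "e5cc9ef2c28f72afaa7b00ab2d94e1b0115c5514dcd39a056c3f368631c2af2f",
    "argos_hydrophobicity.tsv": "7c03a962016f8e7c8d156a79b94f6b14653f9e6a685597259e351f69dedff957",
    "blosum62.tsv": "9ebbccb1a9ceb6413a5e7b0bf09b09a94a9a749e980da6a5f681c7ef2e1be261",
}

# codon -> amino acid, standard genetic code; stops map to '*'
GENETIC_CODE: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    GENETIC_CODE[_stop] = "*"

SYNONYMOUS_FAMILY: dict[str, tuple[str, ...]] = {}
for _aa in AMINO_ACIDS:
    SYNONYMOUS_FAMILY[_aa] = tuple(
        sorted(c for c, a in GENETIC_CODE.items() if a == _aa)
    )


def translate_codon(codon: str) -> str:
    codon = codon.upper().replace("U", "T")
    try:
        return GENETIC_CODE[codon]
    except KeyError:
        raise ValueError(f"not a codon: {codon!r}") from None


def _read_fixture(name: str) -> pd.DataFrame:
    ref = resources.files("polarix.data") / name
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _FIXTURE_SHA256[name]:
        raise RuntimeError(
            f"packaged fixture {name} is corrupted (sha256 {digest})"
        )
    from io import BytesIO

    return pd.read_csv(BytesIO(raw), sep="\t", index_col=0)


@dataclass(frozen=True)
class SubstitutionMatrices:
    """Packaged, checksummed amino-acid scoring tables."""

    grantham: pd.DataFrame
    hydrophobicity: Mapping[str, float]
    blosum62: pd.DataFrame

    def __post_init__(self) -> None:
        for mat in (self.grantham, self.blosum62):
            if set(mat.index) != set(AMINO_ACIDS):
                raise ValueError("matrix must cover the 20 standard amino acids")
            if not np.allclose(mat.values, mat.values.T):
                raise ValueError("substitution matrix must be symmetric")
        if any(self.grantham.values.diagonal() != 0):
            raise ValueError("Grantham diagonal must be 0")


_MATRICES: SubstitutionMatrices | None = None


def load_substitution_matrices() -> SubstitutionMatrices:
    global _MATRICES
    if _MATRICES is None:
        gr = _read_fixture("grantham.tsv").astype(float)
        hyd = _read_fixture("argos_hydrophobicity.tsv")["hydrophobicity"].to_dict()
        b62 = _read_fixture("blosum62.tsv").astype(int)
        _MATRICES = SubstitutionMatrices(grantham=gr, hydrophobicity=hyd, blosum62=b62)
    return _MATRICES


def _check_aa(aa: str) -> str:
    aa = aa.upper()
    if aa not in AMINO_ACIDS:
        raise ValueError(f"not a standard amino acid: {aa!r}")
    return aa


def grantham_distance(aa1: str, aa2: str) -> float:
    """Grantham (composition/polarity/volume) chemical distance; 0 on identity."""
    m = load_substitution_matrices()
    return float(m.grantham.at[_check_aa(aa1), _check_aa(aa2)])


def hydrophobicity_delta(aa1: str, aa2: str) -> float:
    """|dH|: absolute difference on the Argos membrane hydrophobicity scale."""
    m = load_substitution_matrices()
    return abs(m.hydrophobicity[_check_aa(aa1)] - m.hydrophobicity[_check_aa(aa2)])


def blosum62_score(aa1: str, aa2: str) -> int:
    m = load_substitution_matrices()
    return int(m.blosum62.at[_check_aa(aa1), _check_aa(aa2)])


# ---------------------------------------------------------------------------
# codon optimality


@dataclass(frozen=True)
class CodonOptimalityTable:
    """Per-codon usage odds ratio between high- and low-expression genes."""

    odds: Mapping[str, float]
    counts_high: Mapping[str, int]
    counts_low: Mapping[str, int]
    family: Mapping[str, str]  # codon -> amino acid

    def __post_init__(self) -> None:
        if any(o <= 0 for o in self.odds.values()):
            raise ValueError("odds ratios must be positive")

    def optimality(self, codon: str) -> float:
        codon = codon.upper().replace("U", "T")
        try:
            return float(self.odds[codon])
        except KeyError:
            raise ValueError(f"no optimality for codon {codon!r} (stop?)") from None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "codon": c,
                "amino_acid": self.family[c],
                "odds_ratio": self.odds[c],
                "count_high": self.counts_high[c],
                "count_low": self.counts_low[c],
            }
            for c in sorted(self.odds)
        ]
        return pd.DataFrame(rows)


def cds_codons(tx: TranscriptModel) -> list[str]:
    s, e = tx.cds
    cds = tx.seq[s:e].upper().replace("U", "T")
    return [cds[i : i + 3] for i in range(0, len(cds), 3)]


def geometric_mean_expression(
    expression: pd.DataFrame, offset: float = 1.0
) -> pd.Series:
    """Per-gene geometric mean across tissues, with an additive offset.

    ``offset`` (default 1) guards against zeros before taking logs; it is
    applied to every value, so the ranking it induces is monotone in the
    raw values when tissue profiles are proportional.
    """
    vals = expression.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("expression values must be nonnegative")
    gm = np.exp(np.log(vals + offset).mean(axis=1))
    return pd.Series(gm, index=expression.index, name="expression_gm")


def compute_codon_optimality(
    expression: pd.DataFrame,
    transcripts: Mapping[str, TranscriptModel],
    quantile: float = 0.2,
    offset: float = 1.0,
) -> CodonOptimalityTable:
    """Usage odds ratio per codon between expression-quintile gene groups.

    Genes are ranked by the geometric-mean expression; codon counts are
    pooled within the top and bottom ``quantile`` groups. For codon c in
    synonymous family F,
    ``O_c = [(n_H(c)+1/2)/(n_H(F\\c)+1/2)] / [(n_L(c)+1/2)/(n_L(F\\c)+1/2)]``
    (Haldane-Anscombe 0.5 pseudocount on all four cells). Single-codon
    families (Met, Trp) have O_c = 1 by convention; stop codons are
    excluded.
    """
    if len(expression) < 10:
        raise ValueError("need at least 10 genes to form expression quintiles")
    gm = geometric_mean_expression(expression, offset=offset)
    gm = gm.sort_values(kind="mergesort")  # stable: ties broken by gene order
    n_grp = int(np.floor(quantile * len(gm)))
    if n_grp < 1:
        raise ValueError("expression quantile produced an empty group")
    low_genes = list(gm.index[:n_grp])
    high_genes = list(gm.index[-n_grp:])

    by_gene = {g: tx for g, tx in ((t.gene_id, t) for t in transcripts.values())}

    def pooled_counts(genes: list[str]) -> dict[str, int]:
        counts = {c: 0 for c, aa in GENETIC_CODE.items() if aa != "*"}
        for g in genes:
            tx = by_gene.get(g)
            if tx is None:
                raise ValueError(f"no transcript for gene {g}")
            for codon in cds_codons(tx):
                if GENETIC_CODE.get(codon, "*") != "*":
                    counts[codon] += 1
        return counts

    n_high = pooled_counts(high_genes)
    n_low = pooled_counts(low_genes)

    odds: dict[str, float] = {}
    family: dict[str, str] = {}
    for aa in AMINO_ACIDS:
        fam = SYNONYMOUS_FAMILY[aa]
        for c in fam:
            family[c] = aa
            if len(fam) == 1:
                odds[c] = 1.0
                continue
            rest = [x for x in fam if x != c]
            h_c, h_r = n_high[c] + 0.5, sum(n_high[x] for x in rest) + 0.5
            l_c, l_r = n_low[c] + 0.5, sum(n_low[x] for x in rest) + 0.5
            odds[c] = (h_c / h_r) / (l_c / l_r)
    return CodonOptimalityTable(
        odds=odds, counts_high=n_high, counts_low=n_low, family=family
    )


def delta_codon_optimality(
    codon_wt: str,
    codon_mut: str,
    table: CodonOptimalityTable,
    log_scale: bool = False,
) -> float:
    """|dO_codon| for a synonymous substitution (natural odds-ratio scale).

    With ``log_scale`` the difference is taken on log(O) instead.
    """
    cw = codon_wt.upper().replace("U", "T")
    cm = codon_mut.upper().replace("U", "T")
    aw, am = translate_codon(cw), translate_codon(cm)
    if aw == "*" or am == "*":
        raise ValueError("codon optimality undefined for stop codons")
    if aw != am:
        raise ValueError(f"{cw}->{cm} is not synonymous ({aw}->{am})")
    ow, om = table.optimality(cw), table.optimality(cm)
    if log_scale:
        return abs(float(np.log(ow) - np.log(om)))
    return abs(ow - om)
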