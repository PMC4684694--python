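"""Boltzmann-ensemble consequences of a point substitution in an mRNA window.

The model is deliberately minimal: a secondary structure is any pseudoknot-
free (nested) set of base pairs with at least ``min_loop`` unpaired bases in
every hairpin, and its energy is the sum of independent per-pair energies.
Canonical pairs are stabilizing (GC/CG = -3, AU/UA = -2, GU/UG = -1 in
reduced units) and every other pair carries a finite +8 penalty, so the
wild-type and mutant ensembles share the same support and the
Kullback-Leibler divergence between them is always finite.

Because the energy is pair-additive, three exact routes exist and are kept
side by side:

* exhaustive enumeration of all structures (the testing oracle, <= 20 nt);
* Nussinov-style minimization for the MFE and a McCaskill-style
  inside/outside pass for the partition function and the base-pair
  probability (BPP) matrix;
* a closed form for the ensemble relative entropy
  ``D(wt || mut) = ln(Z_mut/Z_wt) + beta * sum_{(i,j) touching the SNP}
  p_wt(i,j) * (e_mut(i,j) - e_wt(i,j))``,
  exact here because only pairs involving the substituted site change
  energy.

Numerics: the inside pass runs in the log domain for the total partition
function; base-pair probabilities use a second inside/outside pass rescaled
by sigma = Z^(1/n) per nucleotide so every intermediate stays O(1) at any
window length. The outside sum over directly-enclosing pairs is maintained
incrementally with one thin matrix product per span, keeping the whole
pass at O(n^3)-ish BLAS work.

Per-variant outputs mirror the three published-style metrics: ensemble
relative entropy (structural entropy), |ddG_MFE| and the Euclidean BPP
distance between alleles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping

import numpy as np

from .io_formats import TranscriptModel

__all__ = [
    "EnergyModel",
    "BPPMatrix",
    "StructuralEffect",
    "extract_window",
    "enumerate_structures",
    "count_structures",
    "mfe",
    "partition_function",
    "log_partition_function",
    "base_pair_probabilities",
    "ensemble_relative_entropy",
    "structural_distance",
    "score_structural_effect",
    "enumeration_reference",
]

_ENUM_MAX_LEN = 20


def _to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


@dataclass(frozen=True)
class EnergyModel:
    """Pair-additive folding parameters in reduced (beta=1) units."""

    pair_energy: Mapping[str, float] = field(
        default_factory=lambda: {"GC": -3.0, "AU": -2.0, "GU": -1.0}
    )
    noncanonical_energy: float = 8.0
    min_loop: int = 3
    beta: float = 1.0

    def __post_init__(self) -> None:
        if self.min_loop < 0:
            raise ValueError("min_loop must be >= 0")
        if self.beta <= 0:
            raise ValueError("beta must be > 0")

    def pair(self, a: str, b: str) -> float:
        """Energy of pairing base ``a`` with base ``b`` (order-free)."""
        e = self.pair_energy.get(a + b)
        if e is None:
            e = self.pair_energy.get(b + a)
        return self.noncanonical_energy if e is None else e

    def energy_matrix(self, seq: str) -> np.ndarray:
        s = _to_rna(seq)
        lut = {}
        for a in "ACGU":
            for b in "ACGU":
                lut[a + b] = self.pair(a, b)
        codes = np.array([lut[a + b] for a in "ACGU" for b in "ACGU"]).reshape(4, 4)
        idx = np.array([("ACGU").index(c) for c in s])
        return codes[np.ix_(idx, idx)] if len(s) else np.zeros((0, 0))

    def shifted(self, c: float) -> "EnergyModel":
        """A model with ``c`` added to every pair energy (incl. penalty)."""
        return EnergyModel(
            pair_energy={k: v + c for k, v in self.pair_energy.items()},
            noncanonical_energy=self.noncanonical_energy + c,
            min_loop=self.min_loop,
            beta=self.beta,
        )


@dataclass(frozen=True)
class BPPMatrix:
    """Upper-triangular base-pair probability matrix of one ensemble."""

    n: int
    p: np.ndarray

    def __post_init__(self) -> None:
        if self.p.shape != (self.n, self.n):
            raise ValueError("BPP matrix shape mismatch")


@dataclass(frozen=True)
class StructuralEffect:
    relative_entropy: float
    mfe_gap: float
    bpp_distance: float
    window: tuple[int, int, int]  # (start0, end0, snp_offset)


# ---------------------------------------------------------------------------
# window extraction


def extract_window(
    tx: TranscriptModel | str, pos0: int, width: int = 150
) -> tuple[str, int]:
    """Cut a ``width``-nt window centred on ``pos0``, truncated at the ends.

    The window is ``[max(0, pos0 - w//2), min(L, pos0 + ceil(w/2)))``; no
    re-centering is done when truncation shortens it, so behaviour near
    transcript ends is deterministic.
    """
    seq = tx.seq if isinstance(tx, TranscriptModel) else tx
    L = len(seq)
    if not 0 <= pos0 < L:
        raise ValueError(f"pos0 {pos0} outside transcript of length {L}")
    if width < 11:
        raise ValueError("window width must be >= 11")
    start = max(0, pos0 - width // 2)
    end = min(L, pos0 + (width - width // 2))
    return seq[start:end], pos0 - start


# ---------------------------------------------------------------------------
# exhaustive enumeration (oracle)


def enumerate_structures(
    seq: str, model: EnergyModel
) -> list[tuple[tuple[tuple[int, int], ...], float]]:
    """All nested structures of ``seq`` with their energies.

    Guarded to <= 20 nt; the structure count grows exponentially. The empty
    structure (energy 0) is always included.
    """
    s = _to_rna(seq)
    n = len(s)
    if n > _ENUM_MAX_LEN:
        raise ValueError(f"enumeration limited to {_ENUM_MAX_LEN} nt, got {n}")
    ml = model.min_loop

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> tuple[tuple[tuple[int, int], ...], ...]:
        # all nested pair sets on s[i..j] inclusive
        if j - i <= ml:
            return ((),)
        out: list[tuple[tuple[int, int], ...]] = []
        out.extend(rec(i + 1, j))  # i unpaired
        for k in range(i + ml + 1, j + 1):  # i paired with k
            for inner in rec(i + 1, k - 1):
                for right in rec(k + 1, j):
                    out.append(((i, k),) + inner + right)
        return tuple(out)

    structures = rec(0, n - 1) if n else ((),)
    rec.cache_clear()
    result = []
    for pairs in structures:
        e = sum(model.pair(s[i], s[j]) for i, j in pairs)
        result.append((tuple(sorted(pairs)), e))
    return result


def count_structures(seq: str, model: EnergyModel) -> int:
    """Number of admissible nested structures, by an independent recursion.

    ``N(i,j) = N(i,j-1) + sum_k N(i,k-1) N(k+1,j-1)`` over ``j-k > min_loop``
    counts by the pairing state of the rightmost base; cross-checks the
    enumeration without listing structures.
    """
    n = len(seq)
    ml = model.min_loop
    N = [[1] * (n + 1) for _ in range(n + 2)]  # N[i][j+1] over s[i..j]

    def get(i: int, j: int) -> int:
        return 1 if j < i else N[i][j + 1]

    for span in range(ml + 1, n):
        for i in range(0, n - span):
            j = i + span
            total = get(i, j - 1)
            for k in range(i, j - ml):
                total += get(i, k - 1) * get(k + 1, j - 1)
            N[i][j + 1] = total
    return get(0, n - 1)


# ---------------------------------------------------------------------------
# MFE (Nussinov-style, pair-additive energies)


def mfe(seq: str, model: EnergyModel) -> tuple[float, tuple[tuple[int, int], ...]]:
    """Minimum-energy structure by O(n^3) dynamic programming.

    Ties are broken toward fewer pairs, then toward the lexicographically
    smallest sorted pair list, so the traceback is deterministic. The empty
    structure is always admissible, hence the MFE is <= 0.
    """
    s = _to_rna(seq)
    n = len(s)
    ml = model.min_loop
    if n == 0:
        return 0.0, ()
    E = model.energy_matrix(s)
    # BE[i, j+1] / BP[i, j+1]: min energy and its pair count on s[i..j]
    BE = np.zeros((n + 2, n + 2))
    BP = np.zeros((n + 2, n + 2), dtype=int)

    def cell_options(i: int, j: int) -> tuple[np.ndarray, np.ndarray]:
        ks = np.arange(i + ml + 1, j + 1)
        pe = E[i, ks] + BE[i + 1, ks] + BE[ks + 1, j + 1]
        pp = 1 + BP[i + 1, ks] + BP[ks + 1, j + 1]
        return pe, pp

    for span in range(ml + 1, n):
        for i in range(0, n - span):
            j = i + span
            ue, up = BE[i + 1, j + 1], BP[i + 1, j + 1]  # i unpaired
            pe, pp = cell_options(i, j)
            emin = pe.min()
            pmin = int(pp[pe == emin].min())
            if (emin, pmin) < (ue, up):
                BE[i, j + 1], BP[i, j + 1] = emin, pmin
            else:
                BE[i, j + 1], BP[i, j + 1] = ue, up

    pairs: list[tuple[int, int]] = []

    def trace(i: int, j: int) -> None:
        while i < j - ml:
            te, tp = BE[i, j + 1], BP[i, j + 1]
            pe, pp = cell_options(i, j)
            hit = np.flatnonzero((pe == te) & (pp == tp))
            if hit.size:  # prefer pairing i, smallest partner first
                k = i + ml + 1 + int(hit[0])
                pairs.append((i, k))
                trace(i + 1, k - 1)
                i = k + 1
            else:
                i += 1

    trace(0, n - 1)
    return float(BE[0, n]), tuple(sorted(pairs))


# ---------------------------------------------------------------------------
# partition function and BPP (McCaskill-style inside/outside)


def _inside_log(seq: str, model: EnergyModel) -> np.ndarray:
    """L[i, j+1] = log partition function on s[i..j]; empty intervals 0."""
    n = len(seq)
    ml = model.min_loop
    wlog = -model.beta * model.energy_matrix(seq)
    L = np.zeros((n + 2, n + 2))
    for span in range(ml + 1, n):
        for i in range(0, n - span):
            j = i + span
            # j unpaired: L[i, j]; j paired with k in [i, j-ml-1]
            v = L[i, i : j - ml] + wlog[i : j - ml, j] + L[i + 1 : j - ml + 1, j]
            m = max(float(v.max()), L[i, j])
            L[i, j + 1] = m + math.log(
                math.exp(L[i, j] - m) + float(np.exp(v - m).sum())
            )
    return L


def log_partition_function(seq: str, model: EnergyModel) -> float:
    n = len(seq)
    if n == 0:
        return 0.0
    return float(_inside_log(_to_rna(seq), model)[0, n])


def partition_function(seq: str, model: EnergyModel) -> float:
    """Z = sum over all admissible structures of exp(-beta * E(s))."""
    return float(math.exp(log_partition_function(seq, model)))


def _ensemble(seq: str, model: EnergyModel) -> tuple[float, np.ndarray]:
    """(log Z, BPP matrix) sharing one inside pass."""
    s = _to_rna(seq)
    n = len(s)
    ml = model.min_loop
    p = np.zeros((n, n))
    if n <= ml:
        return 0.0, p
    L = _inside_log(s, model)
    logZ = float(L[0, n])
    sigma_log = logZ / n
    w = np.exp(-model.beta * model.energy_matrix(s) - 2.0 * sigma_log)
    sig_inv = math.exp(-sigma_log)

    # scaled inside: S[i, j+1] = Z(i,j) / sigma^(j-i+1); empty interval -> 1
    S = np.ones((n + 1, n + 1))
    for span in range(0, n):
        for i in range(0, n - span):
            j = i + span
            total = S[i, j] * sig_inv
            if span > ml:
                total += float(
                    np.dot(
                        S[i, i : j - ml] * w[i : j - ml, j],
                        S[i + 1 : j - ml + 1, j],
                    )
                )
            S[i, j + 1] = total

    # outside by decreasing span. T[a, b] = scaled Z(a+1, b-1) for a < b;
    # the directly-enclosing-pair sum for every cell is C = T' M T' with
    # M(h, l) = p(h, l) / S[h+1, l], maintained incrementally per span.
    T = np.triu(S[1:, :n], 1)
    Tt = T.T.copy()
    C = np.zeros((n, n))
    for span in range(n - 1, ml, -1):
        ii = np.arange(0, n - span)
        jj = ii + span
        zbs = w[ii, jj] * S[ii + 1, jj]  # scaled Z with (i,j) paired
        ext = S[0, ii] * S[jj + 1, n]
        band = zbs * (ext + C[ii, jj])
        p[ii, jj] = band
        m = band / S[ii + 1, jj]
        if span > ml + 1 and m.any():
            # fold this span's pairs into C for the smaller spans
            C += (Tt[:, ii] * m) @ Tt[jj, :]
    np.clip(p, 0.0, 1.0, out=p)
    return logZ, p


def base_pair_probabilities(seq: str, model: EnergyModel) -> BPPMatrix:
    """p(i,j) = ensemble probability that bases i and j are paired."""
    _, p = _ensemble(seq, model)
    return BPPMatrix(n=len(seq), p=p)


# ---------------------------------------------------------------------------
# per-variant metrics


def _check_single_diff(seq_wt: str, seq_mut: str, snp_offset: int) -> bool:
    if len(seq_wt) != len(seq_mut):
        raise ValueError("alleles must give equal-length windows")
    diff = [k for k, (a, b) in enumerate(zip(seq_wt, seq_mut)) if a != b]
    if diff and diff != [snp_offset]:
        raise ValueError(f"sequences differ at {diff}, expected only {snp_offset}")
    return bool(diff)


def _relative_entropy_from(
    logZ_wt: float,
    logZ_mut: float,
    bpp_wt: np.ndarray,
    e_wt: np.ndarray,
    e_mut: np.ndarray,
    snp_offset: int,
    beta: float,
) -> float:
    k = snp_offset
    cross = float(np.dot(bpp_wt[:k, k], e_mut[:k, k] - e_wt[:k, k])) + float(
        np.dot(bpp_wt[k, k + 1 :], e_mut[k, k + 1 :] - e_wt[k, k + 1 :])
    )
    d = (logZ_mut - logZ_wt) + beta * cross
    return 0.0 if -1e-12 < d < 0.0 else float(d)


def ensemble_relative_entropy(
    seq_wt: str,
    seq_mut: str,
    snp_offset: int,
    model: EnergyModel,
    direction: str = "wt||mut",
) -> float:
    """KL divergence D(wt || mut) between the two Boltzmann ensembles (nats).

    Exact under the pair-additive model: only pairs touching the mutated
    site change energy, so
    ``D = ln(Z_mut/Z_wt) + beta * sum p_wt(i,j) [e_mut(i,j) - e_wt(i,j)]``
    over pairs with i or j equal to ``snp_offset``. ``direction`` may be
    flipped to "mut||wt".
    """
    wt, mut = _to_rna(seq_wt), _to_rna(seq_mut)
    if direction == "mut||wt":
        wt, mut = mut, wt
    elif direction != "wt||mut":
        raise ValueError(f"unknown direction {direction!r}")
    if not _check_single_diff(wt, mut, snp_offset):
        return 0.0
    logZ_wt, bpp_wt = _ensemble(wt, model)
    logZ_mut = log_partition_function(mut, model)
    return _relative_entropy_from(
        logZ_wt,
        logZ_mut,
        bpp_wt,
        model.energy_matrix(wt),
        model.energy_matrix(mut),
        snp_offset,
        model.beta,
    )


def structural_distance(bpp_wt: BPPMatrix, bpp_mut: BPPMatrix) -> float:
    """Euclidean distance between upper-triangular BPP matrices."""
    if bpp_wt.n != bpp_mut.n:
        raise ValueError("BPP matrices have different dimensions")
    iu = np.triu_indices(bpp_wt.n, k=1)
    diff = bpp_wt.p[iu] - bpp_mut.p[iu]
    return float(np.sqrt(np.sum(diff * diff)))


def score_structural_effect(
    tx: TranscriptModel | str,
    pos0: int,
    ref: str,
    alt: str,
    model: EnergyModel | None = None,
    width: int = 150,
) -> StructuralEffect:
    """All three structural metrics for substituting ref->alt at ``pos0``."""
    model = model or EnergyModel()
    seq = tx.seq if isinstance(tx, TranscriptModel) else tx
    ref_r, alt_r = _to_rna(ref), _to_rna(alt)
    if _to_rna(seq[pos0]) != ref_r:
        raise ValueError(
            f"reference mismatch at position {pos0}: transcript has "
            f"{seq[pos0]!r}, expected {ref!r}"
        )
    window, offset = extract_window(seq, pos0, width)
    wt = _to_rna(window)
    mut = wt[:offset] + alt_r + wt[offset + 1 :]
    start = pos0 - offset
    win = (start, start + len(wt), offset)
    if wt == mut:
        return StructuralEffect(0.0, 0.0, 0.0, win)
    logZ_wt, p_wt = _ensemble(wt, model)
    logZ_mut, p_mut = _ensemble(mut, model)
    d_kl = _relative_entropy_from(
        logZ_wt,
        logZ_mut,
        p_wt,
        model.energy_matrix(wt),
        model.energy_matrix(mut),
        offset,
        model.beta,
    )
    mfe_wt, _ = mfe(wt, model)
    mfe_mut, _ = mfe(mut, model)
    iu = np.triu_indices(len(wt), k=1)
    diff = p_wt[iu] - p_mut[iu]
    return StructuralEffect(
        relative_entropy=d_kl,
        mfe_gap=float(abs(mfe_wt - mfe_mut)),
        bpp_distance=float(np.sqrt(np.sum(diff * diff))),
        window=win,
    )


# ---------------------------------------------------------------------------
# enumeration-based references (used by tests and the acceptance script)


def enumeration_reference(
    seq_wt: str, seq_mut: str, model: EnergyModel
) -> dict[str, object]:
    """Z, MFE, BPP, D and BPP distance for both alleles by brute force."""
    out: dict[str, object] = {}
    ensembles = {}
    for name, seq in (("wt", seq_wt), ("mut", seq_mut)):
        structs = enumerate_structures(seq, model)
        weights = np.array([math.exp(-model.beta * e) for _, e in structs])
        Z = float(weights.sum())
        n = len(seq)
        bpp = np.zeros((n, n))
        for (pairs, e), wgt in zip(structs, weights):
            for i, j in pairs:
                bpp[i, j] += wgt
        bpp /= Z
        ensembles[name] = (structs, weights / Z)
        out[f"Z_{name}"] = Z
        out[f"mfe_{name}"] = float(min(e for _, e in structs))
        out[f"bpp_{name}"] = bpp
    (s_wt, p_wt), (s_mut, p_mut) = ensembles["wt"], ensembles["mut"]
    q = {pairs: prob for (pairs, _), prob in zip(s_mut, p_mut)}
    out["relative_entropy"] = float(
        sum(p * math.log(p / q[pairs]) for (pairs, _), p in zip(s_wt, p_wt) if p > 0)
    )
    iu = np.triu_indices(len(seq_wt), k=1)
    diff = out["bpp_wt"][iu] - out["bpp_mut"][iu]
    out["bpp_distance"] = float(np.sqrt(np.sum(diff * diff)))
    return out
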