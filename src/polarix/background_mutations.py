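"""Random point mutations matched to the cohort's transition/transversion
ratio, per transcript region — the null background against which observed
SNP consequences are contrasted.

Sites are drawn uniformly (with replacement) within each region; each
region's mutations realize the target ts/tv ratio R by choosing the unique
transition partner with probability R/(R+1) and otherwise one of the two
transversions uniformly. Background mutations carry the same positional
fields as real SNPs (no frequency) and are scored by the very same
protein/RNA operations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import TranscriptModel
from .polarization import PolarizedSNP, classify_site

__all__ = ["BackgroundSpec", "estimate_ts_tv", "generate_background"]

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_BASES = "ACGT"
REGIONS = ("utr5", "cds", "utr3")


@dataclass(frozen=True)
class BackgroundSpec:
    n_total: int
    ts_tv_by_region: Mapping[str, float] = field(
        default_factory=lambda: {r: 2.0 for r in REGIONS}
    )
    seed: int = 0
    n_by_region: Mapping[str, int] | None = None  # overrides proportional split

    def __post_init__(self) -> None:
        if self.n_total < 1:
            raise ValueError("n_total must be >= 1")
        for r, ratio in self.ts_tv_by_region.items():
            if ratio <= 0:
                raise ValueError(f"ts/tv ratio for {r} must be > 0")


def _is_transition(a: str, b: str) -> bool:
    return _TRANSITION[a.upper()] == b.upper()


def estimate_ts_tv(snps: Iterable[PolarizedSNP], region: str | None = None) -> float:
    """Observed transition/transversion ratio of ancestral->derived changes.

    ``region`` restricts to utr5 / cds (syn+nonsyn+nonsense) / utr3. The
    ratio is a property of the unordered allele pair, so it is invariant
    to swapping the ancestral/derived labels.
    """
    ts = tv = 0
    for s in snps:
        if region is not None:
            r = "cds" if s.site_class in ("syn", "nonsyn", "nonsense") else s.site_class
            if r != region:
                continue
        if _is_transition(s.ancestral, s.derived):
            ts += 1
        else:
            tv += 1
    if tv == 0:
        raise ValueError(f"no transversions in region {region!r}: ts/tv undefined")
    if ts == 0:
        raise ValueError(f"no transitions in region {region!r}: ts/tv degenerate")
    return ts / tv


def generate_background(
    transcripts: Mapping[str, TranscriptModel],
    spec: BackgroundSpec,
    tis_window: int = 50,
    ss_margin: int = 3,
) -> pd.DataFrame:
    """Random mutation table with per-region ts/tv matched to ``spec``.

    Counts are allocated to regions proportionally to their aggregate
    length unless ``spec.n_by_region`` gives absolute counts. Duplicated
    sites are allowed. A ratio of ``math.inf`` yields transitions only.
    Columns mirror the scored-SNP schema (site_class, in_tis, in_ss) plus
    ``background=True``; there is no frequency.
    """
    if not transcripts:
        raise ValueError("transcripts must be nonempty")
    rng = np.random.default_rng(spec.seed)
    tx_ids = sorted(transcripts)

    # per-region site pools: (tx index, pos0) addressable uniformly
    pools: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for region in REGIONS:
        tx_l, starts, lens = [], [], []
        for ti, tx_id in enumerate(tx_ids):
            tx = transcripts[tx_id]
            lo, hi = getattr(tx, {"utr5": "utr5", "cds": "cds", "utr3": "utr3"}[region])
            if hi > lo:
                tx_l.append(ti)
                starts.append(lo)
                lens.append(hi - lo)
        pools[region] = (
            np.array(tx_l, dtype=int),
            np.array(starts, dtype=int),
        ) + (np.array(lens, dtype=int),) if tx_l else (None, None, None)

    region_len = {
        r: int(pools[r][2].sum()) if pools[r][0] is not None else 0 for r in REGIONS
    }
    if spec.n_by_region is not None:
        counts = {r: int(spec.n_by_region.get(r, 0)) for r in REGIONS}
    else:
        total_len = sum(region_len.values())
        counts = {
            r: int(round(spec.n_total * region_len[r] / total_len)) for r in REGIONS
        }

    rows = []
    for region in REGIONS:
        n = counts.get(region, 0)
        if n == 0:
            continue
        tx_arr, start_arr, len_arr = pools[region]
        if tx_arr is None:
            raise ValueError(f"no sequence available in region {region}")
        ratio = spec.ts_tv_by_region.get(region, 2.0)
        p_ts = 1.0 if math.isinf(ratio) else ratio / (ratio + 1.0)
        cum = np.cumsum(len_arr)
        sites = rng.integers(0, cum[-1], size=n)
        which = np.searchsorted(cum, sites, side="right")
        offs = sites - np.concatenate(([0], cum[:-1]))[which]
        is_ts = rng.random(n) < p_ts
        for k in range(n):
            tx = transcripts[tx_ids[int(tx_arr[which[k]])]]
            pos0 = int(start_arr[which[k]] + offs[k])
            ref = tx.seq[pos0].upper()
            if is_ts[k]:
                derived = _TRANSITION[ref]
            else:
                tv = [b for b in _BASES if b != ref and b != _TRANSITION[ref]]
                derived = tv[int(rng.integers(2))]
            site_class, in_tis, in_ss = classify_site(
                tx, pos0, ref, derived, tis_window, ss_margin
            )
            rows.append(
                {
                    "mut_id": f"bg_{region}_{k:06d}",
                    "tx_id": tx.tx_id,
                    "pos0": pos0,
                    "ref": ref,
                    "alt": derived,
                    "ancestral": ref,
                    "derived": derived,
                    "region": region,
                    "site_class": site_class,
                    "in_tis": in_tis,
                    "in_ss": in_ss,
                    "is_transition": bool(is_ts[k]),
                    "background": True,
                }
            )
    return pd.DataFrame(rows)
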