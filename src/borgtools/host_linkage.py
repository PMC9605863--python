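"""Abundance-correlation host linkage and copy-ratio summaries.

An extrachromosomal element rises and falls with the population that carries
it, so across enough samples its abundance profile tracks its host's.  This
module correlates every (element, host) pair of length-normalized depth
profiles with two-sided Pearson correlation, controls the false-discovery
rate with Benjamini-Hochberg across all pairs, and calls a pair significant
when r exceeds a threshold (default 0.92) and the adjusted q is below a
ceiling (default 0.05).  Per-sample element:host depth ratios summarize copy
number; ratios above 1 mean more element DNA than host DNA per cell.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class AbundanceMatrix:
    """Element x sample read counts plus element lengths for depth scaling."""

    counts: pd.DataFrame  # rows: elements, columns: samples
    lengths: pd.Series  # bp per element

    def __post_init__(self) -> None:
        if self.counts.shape[1] < 2:
            raise ValueError("need >= 2 samples for correlation analyses")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = self.counts.index.difference(self.lengths.index)
        if len(missing):
            raise ValueError(f"lengths missing for elements: {list(missing)[:5]}")
        self.lengths = self.lengths.loc[self.counts.index].astype(float)
        if (self.lengths <= 0).any():
            raise ValueError("element lengths must be positive")

    @classmethod
    def from_tsv(cls, counts_path, lengths_path) -> "AbundanceMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        lengths = pd.read_csv(lengths_path, sep="\t", index_col=0).iloc[:, 0]
        return cls(counts=counts, lengths=lengths)

    def depth(self, read_length: float = 150.0) -> pd.DataFrame:
        """Approximate per-sample depth: counts * read_length / element length."""
        return self.counts.div(self.lengths, axis=0) * read_length


@dataclass
class HostAssociation:
    borg_id: str
    host_id: str
    pearson_r: float
    p_value: float
    q_value: float
    significant: bool
    best_for_borg: bool = False
    ratio_min: float = math.nan
    ratio_max: float = math.nan


def copy_ratio(
    matrix: AbundanceMatrix,
    borg_id: str,
    host_id: str,
    depth_floor: float = 1.0,
    read_length: float = 150.0,
) -> tuple[float, float, pd.Series]:
    """Per-sample Borg:host depth ratios and their min/max.

    Only samples where the host depth reaches ``depth_floor`` contribute (a
    ratio against a near-absent host is noise).  If the host never reaches the
    floor, the ratio is undefined: (nan, nan, empty series) with a warning.
    """
    depth = matrix.depth(read_length=read_length)
    hd = depth.loc[host_id]
    bd = depth.loc[borg_id]
    ok = hd >= depth_floor
    if not ok.any():
        warnings.warn(
            f"host {host_id} never reaches depth {depth_floor}x; ratio undefined",
            stacklevel=2,
        )
        return math.nan, math.nan, pd.Series(dtype=float)
    series = (bd[ok] / hd[ok]).astype(float)
    return float(series.min()), float(series.max()), series


def correlate(
    matrix: AbundanceMatrix,
    borg_ids: Sequence[str],
    host_ids: Sequence[str],
    r_threshold: float = 0.92,
    q_threshold: float = 0.05,
    normalize: str = "depth",
    read_length: float = 150.0,
    ratio_depth_floor: float = 1.0,
    pairs: Sequence[tuple[str, str]] | None = None,
) -> list[HostAssociation]:
    """Correlate every (Borg, host) abundance pair and call associations.

    Profiles are length-normalized depths by default (``normalize="counts"``
    correlates raw counts).  Two-sided Pearson p-values are BH-adjusted across
    all pairs; a pair is significant iff ``r > r_threshold`` and
    ``q <= q_threshold``.  Zero-variance profiles are excluded with a warning.
    Results are sorted by r (descending) and each Borg's best host is flagged.
    ``pairs`` restricts the test to designated (borg, host) pairs instead of
    the full product (the FDR correction then spans exactly those pairs).
    """
    if normalize not in ("depth", "counts"):
        raise ValueError("normalize must be 'depth' or 'counts'")
    X = matrix.depth(read_length=read_length) if normalize == "depth" else matrix.counts.astype(float)
    pair_iter = pairs if pairs is not None else product(borg_ids, host_ids)
    pairs_out: list[tuple[str, str, float, float]] = []
    for b, h in pair_iter:
        x = X.loc[b].to_numpy(dtype=float)
        y = X.loc[h].to_numpy(dtype=float)
        finite = np.isfinite(x) & np.isfinite(y)
        if finite.sum() < 3:
            raise ValueError(f"pair ({b}, {h}): need >= 3 finite samples")
        x, y = x[finite], y[finite]
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            warnings.warn(
                f"pair ({b}, {h}): zero-variance profile, correlation undefined; excluded",
                stacklevel=2,
            )
            continue
        r, p = stats.pearsonr(x, y)
        pairs_out.append((b, h, float(r), float(p)))
    if not pairs_out:
        return []
    _, qvals, _, _ = multipletests([p for *_ignored, p in pairs_out], method="fdr_bh")
    out: list[HostAssociation] = []
    for (b, h, r, p), q in zip(pairs_out, qvals):
        rmin, rmax, _ = copy_ratio(
            matrix, b, h, depth_floor=ratio_depth_floor, read_length=read_length
        )
        out.append(
            HostAssociation(
                borg_id=b,
                host_id=h,
                pearson_r=r,
                p_value=p,
                q_value=float(q),
                significant=bool(r > r_threshold and q <= q_threshold),
                ratio_min=rmin,
                ratio_max=rmax,
            )
        )
    best: dict[str, HostAssociation] = {}
    for a in out:
        if a.borg_id not in best or a.pearson_r > best[a.borg_id].pearson_r:
            best[a.borg_id] = a
    for a in best.values():
        a.best_for_borg = True
    return sorted(out, key=lambda a: (-a.pearson_r, a.borg_id, a.host_id))


def associations_to_frame(associations: Sequence[HostAssociation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "borg": a.borg_id,
                "host": a.host_id,
                "pearson_r": a.pearson_r,
                "p_value": a.p_value,
                "q_value": a.q_value,
                "significant": a.significant,
                "best_for_borg": a.best_for_borg,
                "ratio_min": a.ratio_min,
                "ratio_max": a.ratio_max,
            }
            for a in associations
        ]
    )
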