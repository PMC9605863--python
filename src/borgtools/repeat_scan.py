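"""Perfect tandem direct-repeat arrays and terminal inverted repeats.

Giant linear archaeal extrachromosomal elements carry two diagnostic repeat
signatures: dozens of genome-wide arrays of *perfect* tandem direct repeats
(units from a few bp up to tens of bp, three or more adjacent copies), and
kilobase-scale inverted repeats terminating both chromosome ends.  This module
finds both from sequence alone.

Tandem arrays are reported in a normalized form:

1. a maximal perfectly periodic region is located (not extendable left or
   right while keeping the period);
2. its repeat unit is the *minimal period* of the region (failure-function
   border arithmetic), so overlapping long self-matches collapse to the true
   short unit;
3. the region is trimmed (left-anchored) to a whole number of unit copies, so
   ``unit_seq * copies`` reconstructs the reported span byte-for-byte.

An array is reported iff its trimmed span is at least ``min_match`` bp and it
has at least ``min_copies`` copies.  Perfection is absolute: one mismatch ends
an array, and positions holding ``N`` (or any non-ACGT code) never match, so
arrays never span Ns.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .genome import LinearGenome, as_genome, encode, poly_prefix_hashes

# Sequences up to this length are scanned at every candidate period; longer
# sequences use seeded candidate periods from duplicated k-mers (see
# _candidate_periods), which is exact for arrays whose unit actually repeats.
_EXHAUSTIVE_LIMIT = 5_000
_SEED_K = 16
# small periods are always scanned, whatever the seeds say (homopolymers and
# microsatellites generate degenerate seed spacings)
_ALWAYS_PERIODS = 32


@dataclass(frozen=True)
class RepeatArray:
    """A resolved perfect tandem direct-repeat array.

    Coordinates are 0-based half-open on the forward strand.  ``context`` and
    ``aa_repeat`` are filled by :func:`classify_context`.
    """

    genome_id: str
    start: int
    end: int
    unit_seq: str
    unit_len: int
    copies: int
    context: str | None = None  # intergenic | within_gene | gene_overlapping
    aa_repeat: bool | None = None

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class InvertedTerminalRepeat:
    """Terminal inverted repeat of a linear genome (arms anchored at the ends)."""

    genome_id: str
    left_arm: tuple[int, int]
    right_arm: tuple[int, int]
    length: int
    perfect: bool


def _minimal_period(b: bytes) -> int:
    """Smallest period of ``b`` via the KMP failure function (n - border)."""
    n = len(b)
    if n == 0:
        return 0
    fail = [0] * n
    k = 0
    for i in range(1, n):
        while k and b[i] != b[k]:
            k = fail[k - 1]
        if b[i] == b[k]:
            k += 1
        fail[i] = k
    return n - fail[-1]


def _true_runs(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Start/end indices (half-open) of maximal runs of True."""
    d = np.diff(mask.astype(np.int8), prepend=np.int8(0), append=np.int8(0))
    return np.flatnonzero(d == 1), np.flatnonzero(d == -1)


def _candidate_periods(codes: np.ndarray, max_p: int, k: int = _SEED_K) -> list[int]:
    """Candidate tandem periods from spacings of duplicated k-mers.

    Any tandem array whose trimmed span reaches ``min_match`` and
    ``min_copies`` repeats each of its unit-phase k-mers at multiples of the
    unit length, so the unit length appears among spacings of identical
    k-mers.  Spacings at lags 1-3 within each duplicate group are collected to
    tolerate units that contain internally repeated k-mers.
    """
    n = len(codes)
    periods: set[int] = set(range(1, min(_ALWAYS_PERIODS, max_p) + 1))
    if n < 2 * k:
        return sorted(periods)
    pref, invpow = poly_prefix_hashes(codes)
    h = (pref[k:] - pref[:-k]) * invpow[: n - k + 1]
    bad = np.concatenate([[0], np.cumsum(codes >= 4)])
    ok = (bad[k:] - bad[: n - k + 1]) == 0
    idx = np.flatnonzero(ok)
    if len(idx) < 2:
        return sorted(periods)
    hv = h[idx]
    order = np.argsort(hv, kind="stable")
    hs = hv[order]
    ps = idx[order].astype(np.int64)
    for lag in (1, 2, 3):
        if lag >= len(hs):
            break
        same = hs[lag:] == hs[:-lag]
        d = ps[lag:] - ps[:-lag]
        good = same & (d > 0) & (d <= max_p)
        if good.any():
            periods.update(int(x) for x in np.unique(d[good]))
    return sorted(periods)


def find_tandem_arrays(
    genome: LinearGenome | str,
    min_match: int = 50,
    min_copies: int = 3,
) -> list[RepeatArray]:
    """Find all perfect tandem direct-repeat arrays in a sequence.

    Parameters
    ----------
    genome : LinearGenome or str
        Sequence to scan (IUPAC DNA; Ns never match).
    min_match : int
        Minimum reported (trimmed) span in bp.  The default of 50 mirrors a
        repeat search floor of 50 nt; units shorter than 50 bp are still
        reported when overlapping matches resolve to a smaller minimal period.
    min_copies : int
        Minimum number of whole unit copies (must be >= 2).

    Returns
    -------
    list of RepeatArray, sorted by start position (then unit length).
    """
    if min_copies < 2:
        raise ValueError("min_copies must be >= 2")
    if min_match < 1:
        raise ValueError("min_match must be >= 1")
    g = as_genome(genome)
    seq = g.seq.upper()
    L = len(seq)
    if L == 0:
        return []
    codes = encode(seq)
    valid = codes < 4
    max_p = L // min_copies
    if max_p < 1:
        return []
    if L <= _EXHAUSTIVE_LIMIT:
        periods: list[int] = list(range(1, max_p + 1))
    else:
        periods = _candidate_periods(codes, max_p)

    found: dict[tuple[int, int, int], RepeatArray] = {}
    for p in periods:
        eq = (codes[:-p] == codes[p:]) & valid[:-p] & valid[p:]
        starts, ends = _true_runs(eq)
        if len(starts) == 0:
            continue
        rl = ends - starts
        # necessary conditions for *this* period; arrays whose minimal period
        # is smaller are discovered at that period directly
        need = max(min_match - p, (min_copies - 1) * p, 1)
        sel = rl >= need
        for s, e in zip(starts[sel], ends[sel]):
            s = int(s)
            t = int(e) + p  # region [s, t) has period p
            if not valid[s:t].all():
                continue
            p2 = _minimal_period(codes[s:t].tobytes())
            # re-extend maximally at the minimal period
            while s > 0 and valid[s - 1] and codes[s - 1] == codes[s - 1 + p2]:
                s -= 1
            while t < L and valid[t] and codes[t] == codes[t - p2]:
                t += 1
            copies = (t - s) // p2
            end = s + copies * p2
            if copies >= min_copies and end - s >= min_match:
                key = (s, end, p2)
                if key not in found:
                    found[key] = RepeatArray(
                        genome_id=g.id,
                        start=s,
                        end=end,
                        unit_seq=seq[s : s + p2],
                        unit_len=p2,
                        copies=copies,
                    )
    return sorted(found.values(), key=lambda a: (a.start, a.unit_len))


def classify_context(array: RepeatArray, genes: pd.DataFrame) -> RepeatArray:
    """Fill genic context and amino-acid-repeat flag for one array.

    ``genes`` uses 0-based half-open ``start``/``end`` columns plus ``strand``
    (and optionally ``contig`` to filter to the array's genome).  The array is
    ``within_gene`` iff fully inside one gene span, ``gene_overlapping`` on
    partial overlap, else ``intergenic``.  ``aa_repeat`` is true iff the array
    sits within a gene, its unit length is a multiple of 3, and its start is
    in frame (frame taken from the gene start on '+' genes and from the gene
    end on '-' genes).
    """
    g = genes
    if g is not None and len(g) and "contig" in g.columns:
        g = g[g["contig"] == array.genome_id]
    context = "intergenic"
    aa = False
    if g is not None and len(g):
        inside = g[(g["start"] <= array.start) & (g["end"] >= array.end)]
        if len(inside):
            context = "within_gene"
            gene = inside.iloc[0]
            if array.unit_len % 3 == 0:
                if gene["strand"] == "+":
                    aa = (array.start - int(gene["start"])) % 3 == 0
                else:
                    aa = (int(gene["end"]) - array.end) % 3 == 0
        else:
            over = g[(g["start"] < array.end) & (g["end"] > array.start)]
            if len(over):
                context = "gene_overlapping"
    return replace(array, context=context, aa_repeat=aa)


def find_terminal_inverted_repeats(
    genome: LinearGenome | str,
    min_len: int = 100,
    max_mismatch_frac: float = 0.0,
) -> InvertedTerminalRepeat | None:
    """Longest terminal inverted repeat anchored at both chromosome ends.

    Returns the longest prefix length ``k`` (capped at half the genome) whose
    reverse complement matches the genome suffix with at most
    ``max_mismatch_frac * k`` mismatches, provided ``k >= min_len``; ``None``
    otherwise (including genomes shorter than ``2 * min_len``).
    """
    g = as_genome(genome)
    if g.topology != "linear":
        raise ValueError("terminal inverted repeats are defined for linear genomes")
    L = len(g.seq)
    if L < 2 * min_len:
        return None
    c = encode(g.seq.upper()).astype(np.int16)
    half = L // 2
    rc = 3 - c[::-1]  # complement of reversed sequence; invalid codes go < 0
    mism = (c[:half] != rc[:half]) | (c[:half] > 3) | (rc[:half] < 0)
    mis = np.cumsum(mism)
    ks = np.arange(1, half + 1)
    ok = mis <= max_mismatch_frac * ks
    hits = np.flatnonzero(ok)
    if len(hits) == 0:
        return None
    k = int(ks[hits[-1]])
    if k < min_len:
        return None
    return InvertedTerminalRepeat(
        genome_id=g.id,
        left_arm=(0, k),
        right_arm=(L - k, L),
        length=k,
        perfect=bool(mis[k - 1] == 0),
    )


def arrays_to_frame(arrays: list[RepeatArray]) -> pd.DataFrame:
    """Tabulate arrays (0-based half-open coordinates, one row per array)."""
    return pd.DataFrame(
        [
            {
                "genome": a.genome_id,
                "start": a.start,
                "end": a.end,
                "unit_len": a.unit_len,
                "copies": a.copies,
                "unit_seq": a.unit_seq,
                "context": a.context,
                "aa_repeat": a.aa_repeat,
            }
            for a in arrays
        ],
        columns=[
            "genome",
            "start",
            "end",
            "unit_len",
            "copies",
            "unit_seq",
            "context",
            "aa_repeat",
        ],
    )
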