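"""Independent brute-force oracles used to validate the implementation.

These deliberately avoid the implementation's algorithms: tandem arrays are
found by walking every period at every position with per-character
comparisons and a naive slice-compare minimal period; ITRs, overlaps and
spacer matches by direct scanning.  They share only the *definitions*
(maximality, minimal-period unit, left-anchored trimming to whole copies,
N never matches) — not the code paths.
"""

from __future__ import annotations


def naive_minimal_period(s: str) -> int:
    """Smallest q such that s[i] == s[i-q] for all i >= q (slice compare)."""
    n = len(s)
    for q in range(1, n + 1):
        if s[q:] == s[:-q] or q == n:
            return q
    return n


def brute_force_tandem_arrays(seq: str, min_match: int = 50, min_copies: int = 3):
    """All normalized perfect tandem arrays, by exhaustive period enumeration.

    Returns a set of (start, end, unit_len, copies, unit_seq) tuples.
    """
    seq = seq.upper()
    L = len(seq)
    ok = [c in "ACGT" for c in seq]
    found = {}
    max_p = L // min_copies
    for p in range(1, max_p + 1):
        j = 0
        while j < L - p:
            if ok[j] and ok[j + p] and seq[j] == seq[j + p]:
                s = j
                while j < L - p and ok[j] and ok[j + p] and seq[j] == seq[j + p]:
                    j += 1
                t = j + p  # region [s, t) has period p
                # necessary conditions at this period; any qualifying array is
                # also seen directly at its own minimal period, where the run
                # covers its whole span
                if (j - s) < max(min_match - p, (min_copies - 1) * p):
                    continue
                if not all(ok[s:t]):
                    continue
                p2 = naive_minimal_period(seq[s:t])
                s2, t2 = s, t
                while s2 > 0 and ok[s2 - 1] and seq[s2 - 1] == seq[s2 - 1 + p2]:
                    s2 -= 1
                while t2 < L and ok[t2] and seq[t2] == seq[t2 - p2]:
                    t2 += 1
                copies = (t2 - s2) // p2
                end = s2 + copies * p2
                if copies >= min_copies and end - s2 >= min_match:
                    key = (s2, end, p2)
                    if key not in found:
                        found[key] = (s2, end, p2, copies, seq[s2 : s2 + p2])
            else:
                j += 1
    return set(found.values())


_RC = {"A": "T", "C": "G", "G": "C", "T": "A"}


def slow_revcomp(seq: str) -> str:
    return "".join(_RC.get(c, "N") for c in reversed(seq.upper()))


def brute_force_itr(seq: str, min_len: int = 100):
    """Longest k >= min_len with seq[:k] == revcomp(seq[-k:]); None if absent."""
    L = len(seq)
    if L < 2 * min_len:
        return None
    for k in range(L // 2, min_len - 1, -1):
        if seq[:k] == slow_revcomp(seq[L - k :]):
            return k
    return None


def brute_force_cxxch(protein: str):
    """1-based positions of non-overlapping CxxCH motifs, greedy left-to-right."""
    p = protein.upper()
    out = []
    i = 0
    while i + 5 <= len(p):
        if p[i] == "C" and p[i + 3] == "C" and p[i + 4] == "H":
            out.append(i + 1)
            i += 5
        else:
            i += 1
    return out


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y or x not in "ACGT")


def brute_force_spacer_matches(
    spacers, targets, min_len: int = 25, primary_mm: int = 1, extended_mm: int = 3
):
    """Two-tier spacer matching by sliding-window Hamming scan.

    ``spacers``: iterable of (spacer_id, array_id, seq); ``targets``: iterable
    of (target_id, seq).  Returns a set of
    (spacer_id, target_id, start_on_forward, strand, mismatches, tier).
    """
    hits = []
    primaries = set()
    for tid, tseq in targets:
        tseq = tseq.upper()
        L = len(tseq)
        for sid, aid, sseq in spacers:
            sseq = sseq.upper()
            s = len(sseq)
            if s < min_len:
                continue
            for strand in "+-":
                scan = tseq if strand == "+" else slow_revcomp(tseq)
                for off in range(L - s + 1):
                    mm = _hamming(sseq, scan[off : off + s])
                    if mm <= extended_mm:
                        start = off if strand == "+" else L - off - s
                        hits.append((sid, aid, tid, start, strand, s, mm))
                        if s > 24 and mm <= primary_mm:
                            primaries.add((aid, tid))
    out = set()
    for sid, aid, tid, start, strand, s, mm in hits:
        if s > 24 and mm <= primary_mm:
            out.add((sid, tid, start, strand, mm, "primary"))
        elif (aid, tid) in primaries:
            out.add((sid, tid, start, strand, mm, "extended"))
    return out


def brute_force_suffix_prefix(a: str, b: str) -> int:
    """Longest suffix of a equal to a prefix of b, checked from the top down."""
    for k in range(min(len(a), len(b)), 0, -1):
        if a[-k:] == b[:k]:
            return k
    return 0
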