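"""Multihaem-cytochrome motif counting and CRISPR spacer-target matching.

Multihaem cytochromes (MHCs) — the electron conduits of extracellular
respiration — are recognized by their haem-binding CxxCH motifs: a protein
with three or more is called an MHC.  Motifs are counted greedily left to
right without overlap (haem-binding motifs cannot share cysteines).

CRISPR spacers record past encounters between an element and its targets.
Matching here is ungapped over the full spacer length, on both target
strands, with the two-tier mismatch rule: a *primary* hit needs an alignment
length of more than 24 bp with at most one mismatch; once a spacer array has
a primary hit in a target, the same target is re-searched for the array's
remaining spacers at up to three mismatches (*extended* hits).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genome import LinearGenome, as_genome, encode

_CXXCH = re.compile(r"C..CH")


@dataclass(frozen=True)
class MotifReport:
    protein_id: str
    n_cxxch: int
    positions: tuple[int, ...]  # 1-based residue index of each motif's first C
    is_mhc: bool


@dataclass(frozen=True)
class Spacer:
    spacer_id: str
    array_id: str
    seq: str


@dataclass(frozen=True)
class SpacerMatch:
    spacer_id: str
    array_id: str
    target_id: str
    target_start: int  # 0-based on the forward strand of the target
    strand: str
    align_length: int
    mismatches: int
    tier: str  # primary | extended


def count_cxxch(protein: str, protein_id: str = "") -> MotifReport:
    """Count non-overlapping CxxCH motifs in one protein.

    The motif is C, any, any, C, H over five residues; C and H positions must
    match literally (so X never satisfies them) while the middle two may be
    any residue.  Matches are consumed greedily left to right.
    """
    s = protein.upper()
    positions = tuple(m.start() + 1 for m in _CXXCH.finditer(s))
    n = len(positions)
    return MotifReport(protein_id=protein_id, n_cxxch=n, positions=positions, is_mhc=n >= 3)


def scan_proteome(
    proteins: Mapping[str, str] | Iterable[tuple[str, str]],
) -> tuple[list[MotifReport], dict]:
    """Motif reports for every protein plus an MHC summary.

    ``proteins`` is a mapping or an iterable of (id, sequence) pairs;
    duplicate ids are an error.  The summary gives the number of proteins,
    the number flagged as MHCs and the maximum motif count per protein.
    """
    items = list(proteins.items()) if isinstance(proteins, Mapping) else list(proteins)
    seen: set[str] = set()
    reports: list[MotifReport] = []
    for pid, seq in items:
        if pid in seen:
            raise ValueError(f"duplicate protein id: {pid}")
        seen.add(pid)
        reports.append(count_cxxch(seq, protein_id=pid))
    summary = {
        "n_proteins": len(reports),
        "n_mhc": sum(r.is_mhc for r in reports),
        "max_cxxch": max((r.n_cxxch for r in reports), default=0),
    }
    return reports, summary


def _hamming_hits(
    spacer_codes: np.ndarray, target_codes: np.ndarray, max_mm: int
) -> list[tuple[int, int]]:
    """(offset, mismatches) of all full-length ungapped windows with <= max_mm."""
    s = len(spacer_codes)
    L = len(target_codes)
    if L < s:
        return []
    windows = np.lib.stride_tricks.sliding_window_view(target_codes, s)
    mism = (windows != spacer_codes).sum(axis=1)
    hits = np.flatnonzero(mism <= max_mm)
    return [(int(i), int(mism[i])) for i in hits]


def match_spacers(
    spacers: Sequence[Spacer],
    targets: Sequence[LinearGenome] | Mapping[str, str],
    min_len: int = 25,
    primary_mm: int = 1,
    extended_mm: int = 3,
) -> list[SpacerMatch]:
    """Two-tier ungapped spacer-to-target matching on both strands.

    Pass 1 retains primary hits (alignment length > 24 bp, at most
    ``primary_mm`` mismatches).  Pass 2 re-scans each target in which an
    array already has a primary hit, retaining that array's additional hits
    at up to ``extended_mm`` mismatches.  Spacers shorter than ``min_len``
    are skipped with a warning; ambiguous bases never match.  Coordinates are
    reported on the forward strand of the target.
    """
    if isinstance(targets, Mapping):
        target_list = [as_genome(seq, default_id=tid) for tid, seq in targets.items()]
    else:
        target_list = [as_genome(t) for t in targets]

    usable: list[Spacer] = []
    for sp in spacers:
        if len(sp.seq) < min_len:
            warnings.warn(
                f"spacer {sp.spacer_id} shorter than {min_len} bp; skipped", stacklevel=2
            )
            continue
        usable.append(sp)

    # precompute encodings; spacer ambiguity codes are remapped so they never
    # equal anything (including target Ns)
    sp_codes = {}
    for sp in usable:
        c = encode(sp.seq.upper()).copy()
        c[c >= 4] = 5
        sp_codes[sp.spacer_id] = c

    all_hits: list[SpacerMatch] = []
    primary_keys: set[tuple[str, str]] = set()  # (array_id, target_id)
    for tg in target_list:
        fwd = encode(tg.seq.upper())
        L = len(fwd)
        rev = fwd[::-1].copy()
        acgt = rev < 4
        rev[acgt] = 3 - rev[acgt]
        for sp in usable:
            s = len(sp.seq)
            for strand, tcodes in (("+", fwd), ("-", rev)):
                for off, mm in _hamming_hits(sp_codes[sp.spacer_id], tcodes, extended_mm):
                    start = off if strand == "+" else L - off - s
                    all_hits.append(
                        SpacerMatch(
                            spacer_id=sp.spacer_id,
                            array_id=sp.array_id,
                            target_id=tg.id,
                            target_start=start,
                            strand=strand,
                            align_length=s,
                            mismatches=mm,
                            tier="candidate",
                        )
                    )
                    if s > 24 and mm <= primary_mm:
                        primary_keys.add((sp.array_id, tg.id))

    retained: list[SpacerMatch] = []
    for h in all_hits:
        if h.align_length > 24 and h.mismatches <= primary_mm:
            retained.append(
                SpacerMatch(
                    h.spacer_id, h.array_id, h.target_id, h.target_start, h.strand,
                    h.align_length, h.mismatches, "primary",
                )
            )
        elif h.mismatches <= extended_mm and (h.array_id, h.target_id) in primary_keys:
            retained.append(
                SpacerMatch(
                    h.spacer_id, h.array_id, h.target_id, h.target_start, h.strand,
                    h.align_length, h.mismatches, "extended",
                )
            )
    return sorted(
        retained, key=lambda m: (m.target_id, m.target_start, m.spacer_id, m.strand)
    )
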