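"""The five-criterion Borg screen, candidate binning and end-overlap joins.

Once the features of complete Borg genomes are known, related fragments are
recognized in new assemblies by five lines of evidence:

1. credible partial alignment to a complete reference Borg (immediate target);
2. no taxonomic profile even at domain level (strict-majority voting);
3. GC content in the 30-35% band;
4. three or more perfect tandem direct-repeat regions on the fragment;
5. more best hits to *Methanoperedens* proteins than to any other genus.

Fragments meeting criterion 1 are classified ``target`` outright; fragments
meeting most (>= ``candidate_min`` of the other four) are ``candidate`` and
are binned with co-sampled fragments of similar coverage and GC.  Perfect
suffix-prefix overlaps between bin members are reported as join suggestions —
never auto-applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import LinearGenome, encode, poly_prefix_hashes, revcomp
from .repeat_scan import RepeatArray, find_tandem_arrays
from .taxonomy_voting import TaxonomyProfile, genus_dominance, profile_contigs


@dataclass
class ContigFeatures:
    """Per-contig evidence consumed by :func:`evaluate_criteria`."""

    contig_id: str
    length: int
    gc: float
    coverage: float
    n_tandem_arrays: int
    taxonomy: TaxonomyProfile | None = None
    ref_aligned_fraction: float = 0.0


@dataclass
class BorgCriteriaResult:
    contig_id: str
    c1_ref_alignment: bool
    c2_no_domain: bool
    c3_gc_in_range: bool
    c4_repeat_arrays: bool
    c5_genus_dominance: bool
    n_other_criteria_met: int
    classification: str  # target | candidate | rejected


@dataclass
class Bin:
    bin_id: str
    members: list[str]
    coverage_centroid: float
    gc_centroid: float
    joins: list["Join"] = field(default_factory=list)


@dataclass(frozen=True)
class Join:
    """A suggested perfect end-overlap join: suffix of a (oriented) matches
    prefix of b (oriented)."""

    a_id: str
    a_strand: str
    b_id: str
    b_strand: str
    overlap: int


def evaluate_criteria(
    f: ContigFeatures,
    gc_range: tuple[float, float] = (0.30, 0.35),
    min_arrays: int = 3,
    candidate_min: int = 3,
    ref_min_fraction: float = 0.10,
    ref_min_bp: int = 5_000,
    host_genus: str = "Methanoperedens",
) -> BorgCriteriaResult:
    """Apply the five screening criteria to one contig.

    Criterion 1 ("credible partial alignment") is quantified as at least
    ``ref_min_fraction`` of the contig, or at least ``ref_min_bp``, aligned to
    a reference complete Borg (the caller supplies ``ref_aligned_fraction``;
    0 when no references exist).  Criterion 3 uses a closed GC interval.
    A missing taxonomy profile fails criteria 2 and 5 with a warning.
    """
    aligned_bp = f.ref_aligned_fraction * f.length
    c1 = f.ref_aligned_fraction > 0 and (
        f.ref_aligned_fraction >= ref_min_fraction or aligned_bp >= ref_min_bp
    )
    if f.taxonomy is None:
        warnings.warn(
            f"contig {f.contig_id}: no taxonomy profile; criteria 2 and 5 evaluate False",
            stacklevel=2,
        )
        c2 = c5 = False
    else:
        c2 = f.taxonomy.domain_call == "no_domain"
        c5 = genus_dominance(f.taxonomy, genus=host_genus)
    c3 = gc_range[0] <= f.gc <= gc_range[1]
    c4 = f.n_tandem_arrays >= min_arrays
    n_other = int(c2) + int(c3) + int(c4) + int(c5)
    if c1:
        classification = "target"
    elif n_other >= candidate_min:
        classification = "candidate"
    else:
        classification = "rejected"
    return BorgCriteriaResult(
        contig_id=f.contig_id,
        c1_ref_alignment=bool(c1),
        c2_no_domain=bool(c2),
        c3_gc_in_range=bool(c3),
        c4_repeat_arrays=bool(c4),
        c5_genus_dominance=bool(c5),
        n_other_criteria_met=n_other,
        classification=classification,
    )


def compute_contig_features(
    genomes: Sequence[LinearGenome],
    genes: pd.DataFrame,
    coverage: Mapping[str, float] | pd.Series,
    repeats: Mapping[str, Sequence[RepeatArray]] | None = None,
    ref_aligned: Mapping[str, float] | None = None,
    min_match: int = 50,
    min_copies: int = 3,
    denominator: str = "all_genes",
) -> list[ContigFeatures]:
    """Assemble :class:`ContigFeatures` for a set of contigs.

    Runs the tandem-array scan when ``repeats`` is not supplied and votes a
    taxonomy profile per contig from the gene table.  Arrays are counted with
    >= ``min_copies`` copies each (the scan's own reporting rule).
    """
    profiles = profile_contigs(genes, denominator=denominator)
    feats = []
    for g in genomes:
        if repeats is not None:
            arrays = repeats.get(g.id, [])
        else:
            arrays = find_tandem_arrays(g, min_match=min_match, min_copies=min_copies)
        feats.append(
            ContigFeatures(
                contig_id=g.id,
                length=len(g.seq),
                gc=g.gc,
                coverage=float(coverage[g.id]),
                n_tandem_arrays=len(arrays),
                taxonomy=profiles.get(g.id),
                ref_aligned_fraction=float(ref_aligned.get(g.id, 0.0)) if ref_aligned else 0.0,
            )
        )
    return feats


def bin_candidates(
    candidates: Sequence[ContigFeatures],
    cov_tol: float = 0.20,
    gc_tol: float = 0.02,
) -> list[Bin]:
    """Group candidate contigs by coverage and GC (single linkage).

    Two contigs link when their coverages differ by at most ``cov_tol``
    relative to their mean *and* their GC differs by at most ``gc_tol``.
    Deterministic and input-order independent: contigs are processed sorted
    by id and bins are numbered by their smallest member id.
    """
    feats = sorted(candidates, key=lambda f: f.contig_id)
    n = len(feats)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            ci, cj = feats[i].coverage, feats[j].coverage
            mean_cov = 0.5 * (ci + cj)
            if mean_cov <= 0:
                cov_ok = ci == cj
            else:
                cov_ok = abs(ci - cj) <= cov_tol * mean_cov
            if cov_ok and abs(feats[i].gc - feats[j].gc) <= gc_tol:
                parent[find(i)] = find(j)
    groups: dict[int, list[ContigFeatures]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(feats[i])
    ordered = sorted(groups.values(), key=lambda g: g[0].contig_id)
    bins = []
    for k, members in enumerate(ordered, start=1):
        bins.append(
            Bin(
                bin_id=f"bin_{k:03d}",
                members=[m.contig_id for m in members],
                coverage_centroid=float(np.mean([m.coverage for m in members])),
                gc_centroid=float(np.mean([m.gc for m in members])),
            )
        )
    return bins


def _suffix_prefix_overlap(a: str, b: str) -> int:
    """Length of the longest suffix of ``a`` equal to a prefix of ``b``.

    Rolling-hash candidates checked from the longest down, each verified by
    direct string comparison before acceptance.
    """
    cap = min(len(a), len(b))
    if cap == 0:
        return 0
    ca = encode(a.upper())
    cb = encode(b.upper())
    pref_a, inv_a = poly_prefix_hashes(ca)
    pref_b, _ = poly_prefix_hashes(cb)
    n = len(a)
    ks = np.arange(1, cap + 1)
    ha = (pref_a[n] - pref_a[n - ks]) * inv_a[n - ks]
    hb = pref_b[1 : cap + 1]
    for k in ks[ha == hb][::-1]:
        k = int(k)
        if a[n - k :] == b[:k]:
            return k
    return 0


def find_end_overlaps(
    bin_or_members: Bin | Sequence[str],
    sequences: Mapping[str, str],
    min_overlap: int = 100,
) -> list[Join]:
    """Perfect suffix-prefix overlaps (>= ``min_overlap``) between bin members.

    All four oriented adjacencies of each unordered pair are tested
    (A+ then B+, B+ then A+, A+ then B-, A- then B+); reverse-complement duals
    are not double-reported.  Joins are suggestions only, sorted by overlap
    length (descending) then ids.
    """
    members = (
        sorted(bin_or_members.members)
        if isinstance(bin_or_members, Bin)
        else sorted(bin_or_members)
    )
    joins: list[Join] = []
    for i in range(len(members)):
        for j in range(i + 1, len(members)):
            a, b = members[i], members[j]
            sa, sb = sequences[a], sequences[b]
            rb = revcomp(sb)
            ra = revcomp(sa)
            for a_id, a_strand, b_id, b_strand, x, y in (
                (a, "+", b, "+", sa, sb),
                (b, "+", a, "+", sb, sa),
                (a, "+", b, "-", sa, rb),
                (a, "-", b, "+", ra, sb),
            ):
                k = _suffix_prefix_overlap(x, y)
                if k >= min_overlap:
                    joins.append(Join(a_id, a_strand, b_id, b_strand, k))
    return sorted(joins, key=lambda j: (-j.overlap, j.a_id, j.b_id, j.a_strand, j.b_strand))
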