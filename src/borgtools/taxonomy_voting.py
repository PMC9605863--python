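"""Contig-level taxonomy by per-gene best-hit voting.

Novel extrachromosomal elements betray themselves taxonomically: most of
their genes have no database hit at all, so no rank — not even domain —
reaches a strict majority, yet among the genes that *do* hit something the
plurality points at the host genus.  This module implements that voting
scheme: at each of the seven ranks (domain..species) a label is called iff it
receives strictly more than 50% of the votes, with no-hit genes counted in
the denominator by default (exactly what leaves heavily novel contigs with
``no_domain``).  A dialect switch (``denominator="hits_only"``) restricts the
denominator to genes with a label at the rank.

Hits are assumed to be pre-filtered upstream by the homology search's E-value
floor; a gene with no acceptable hit carries the path ``"none"``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")
_GENUS = RANKS.index("genus")


@dataclass(frozen=True)
class TaxPath:
    """A 7-rank taxonomy path (domain -> species); any suffix may be "none"."""

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(RANKS):
            raise ValueError(f"expected {len(RANKS)} ranks, got {len(self.labels)}")
        seen_none = False
        for lab in self.labels:
            if lab == "none":
                seen_none = True
            elif seen_none:
                raise ValueError(
                    "a label below an unassigned rank is invalid: " + ";".join(self.labels)
                )

    @classmethod
    def parse(cls, text: object) -> "TaxPath":
        """Parse a semicolon path; None/NaN/""/"none" all mean no hit."""
        if text is None or (isinstance(text, float) and pd.isna(text)):
            return cls(("none",) * len(RANKS))
        s = str(text).strip()
        if s == "" or s.lower() == "none":
            return cls(("none",) * len(RANKS))
        parts = [p.strip() or "none" for p in s.split(";")]
        if len(parts) > len(RANKS):
            raise ValueError(f"too many ranks in taxonomy path: {s!r}")
        parts += ["none"] * (len(RANKS) - len(parts))
        return cls(tuple(parts))

    @property
    def has_hit(self) -> bool:
        return self.labels[0] != "none"


@dataclass
class TaxonomyProfile:
    """Voting outcome for one contig."""

    contig_id: str
    n_genes: int
    n_genes_with_hits: int
    calls: dict = field(default_factory=dict)  # rank -> (label, vote fraction) | None
    domain_call: str = "no_domain"
    top_genus: str | None = None
    top_genus_gene_count: int = 0
    runner_up_genus_gene_count: int = 0


def vote_taxonomy(
    gene_hits: Iterable[TaxPath | str | None],
    contig_id: str = "",
    denominator: str = "all_genes",
) -> TaxonomyProfile:
    """Vote a taxonomy profile for one contig from per-gene best-hit paths.

    At each rank the winning label is assigned iff its vote count strictly
    exceeds half the denominator (``all_genes``: every gene, including no-hit
    genes; ``hits_only``: genes labelled at that rank).  Exact 50% and ties
    yield no call.  ``domain_call`` is the winning domain or ``"no_domain"``.
    The genus tally (top genus, top and runner-up gene counts) ignores no-hit
    genes and is used for the host-genus dominance criterion.
    """
    if denominator not in ("all_genes", "hits_only"):
        raise ValueError("denominator must be 'all_genes' or 'hits_only'")
    paths = [h if isinstance(h, TaxPath) else TaxPath.parse(h) for h in gene_hits]
    n = len(paths)
    prof = TaxonomyProfile(
        contig_id=contig_id,
        n_genes=n,
        n_genes_with_hits=sum(p.has_hit for p in paths),
    )
    for r, rank in enumerate(RANKS):
        labels = [p.labels[r] for p in paths if p.labels[r] != "none"]
        denom = n if denominator == "all_genes" else len(labels)
        call = None
        if labels and denom > 0:
            top_label, top_count = Counter(labels).most_common(1)[0]
            if top_count > 0.5 * denom:
                call = (top_label, top_count / denom)
        prof.calls[rank] = call
    if prof.calls["domain"] is not None:
        prof.domain_call = prof.calls["domain"][0]
    genus_counts = Counter(
        p.labels[_GENUS] for p in paths if p.labels[_GENUS] != "none"
    )
    if genus_counts:
        ranked = genus_counts.most_common()
        top_count = ranked[0][1]
        winners = sorted(lab for lab, c in ranked if c == top_count)
        prof.top_genus = winners[0]
        prof.top_genus_gene_count = top_count
        if len(winners) > 1:
            prof.runner_up_genus_gene_count = top_count
        elif len(ranked) > 1:
            prof.runner_up_genus_gene_count = ranked[1][1]
    return prof


def genus_dominance(profile: TaxonomyProfile, genus: str = "Methanoperedens") -> bool:
    """True iff ``genus`` has strictly more best hits than any other genus."""
    return (
        profile.top_genus == genus
        and profile.top_genus_gene_count > profile.runner_up_genus_gene_count
    )


def profile_contigs(
    genes: pd.DataFrame,
    denominator: str = "all_genes",
) -> dict[str, TaxonomyProfile]:
    """Vote a profile for every contig in a gene table.

    ``genes`` needs columns ``contig`` and ``best_hit_taxonomy`` (semicolon
    7-rank path or "none").
    """
    out: dict[str, TaxonomyProfile] = {}
    for contig, sub in genes.groupby("contig", sort=True):
        out[str(contig)] = vote_taxonomy(
            sub["best_hit_taxonomy"].tolist(), contig_id=str(contig), denominator=denominator
        )
    return out
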