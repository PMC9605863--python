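"""File formats: FASTA via Biopython, tab-separated tables via pandas.

Conventions: gene and repeat coordinates are 0-based half-open in memory and
1-based inclusive in emitted/consumed ``.tsv`` reports; ``.bed`` emissions are
0-based half-open.  Spacer FASTA headers carry their CRISPR array id as a
``array:NAME`` token in the description.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .borg_screen import Bin, BorgCriteriaResult, Join
from .genome import LinearGenome
from .host_linkage import HostAssociation, associations_to_frame
from .motif_crispr import MotifReport, Spacer, SpacerMatch
from .repeat_scan import RepeatArray
from .skew_replichore import SkewProfile
from .taxonomy_voting import RANKS, TaxonomyProfile


# -- FASTA ------------------------------------------------------------------

def read_fasta(path: str | Path, topology: str = "linear") -> list[LinearGenome]:
    return [
        LinearGenome(id=rec.id, seq=str(rec.seq).upper(), topology=topology, source=str(path))
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(genomes: Sequence[LinearGenome], path: str | Path) -> None:
    records = [SeqRecord(Seq(g.seq), id=g.id, description="") for g in genomes]
    SeqIO.write(records, str(path), "fasta")


def write_protein_fasta(proteins: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=pid, description="") for pid, s in proteins.items()]
    SeqIO.write(records, str(path), "fasta")


def read_protein_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_spacers_fasta(path: str | Path) -> list[Spacer]:
    """Spacers with array ids parsed from an ``array:NAME`` description token."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        array_id = rec.id
        for token in rec.description.split():
            if token.startswith("array:"):
                array_id = token[len("array:"):]
        out.append(Spacer(spacer_id=rec.id, array_id=array_id, seq=str(rec.seq).upper()))
    return out


# -- gene tables ------------------------------------------------------------

def write_genes_tsv(genes: pd.DataFrame, path: str | Path) -> None:
    out = genes.copy()
    out["start"] = out["start"] + 1  # 1-based inclusive on disk
    out.to_csv(path, sep="\t", index=False)


def read_genes_tsv(path: str | Path) -> pd.DataFrame:
    genes = pd.read_csv(path, sep="\t")
    genes["start"] = genes["start"] - 1  # back to 0-based half-open
    return genes


# -- repeats ----------------------------------------------------------------

def write_repeats_tsv(arrays: Sequence[RepeatArray], path: str | Path) -> None:
    rows = [
        {
            "genome": a.genome_id,
            "start": a.start + 1,
            "end": a.end,
            "unit_len": a.unit_len,
            "copies": a.copies,
            "unit_seq": a.unit_seq,
            "context": a.context if a.context is not None else "",
            "aa_repeat": a.aa_repeat if a.aa_repeat is not None else "",
        }
        for a in arrays
    ]
    pd.DataFrame(
        rows,
        columns=["genome", "start", "end", "unit_len", "copies", "unit_seq", "context", "aa_repeat"],
    ).to_csv(path, sep="\t", index=False)


def write_repeats_bed(arrays: Sequence[RepeatArray], path: str | Path) -> None:
    with open(path, "w") as fh:
        for a in arrays:
            name = f"unit{a.unit_len}x{a.copies}"
            fh.write(f"{a.genome_id}\t{a.start}\t{a.end}\t{name}\n")


# -- skew / replichores -----------------------------------------------------

def write_skew_tsv(profile: SkewProfile, path: str | Path) -> None:
    pd.DataFrame(
        {
            "center": profile.window_centers,
            "skew": profile.skew,
            "cumulative": profile.cumulative[
                pd.Index(profile.window_centers).clip(0, len(profile.cumulative) - 1)
            ],
        }
    ).to_csv(path, sep="\t", index=False)


def write_replichores_tsv(profile: SkewProfile, path: str | Path) -> None:
    rows = []
    if profile.replichores:
        for k, rep in enumerate(profile.replichores, 1):
            rows.append(
                {
                    "genome": profile.genome_id,
                    "replichore": k,
                    "start": rep.start + 1,
                    "end": rep.end,
                    "leading_strand": rep.leading_strand,
                    "terminus": profile.terminus,
                    "flag": profile.flag or "",
                }
            )
    else:
        rows.append(
            {
                "genome": profile.genome_id,
                "replichore": "",
                "start": "",
                "end": "",
                "leading_strand": "",
                "terminus": profile.terminus if profile.terminus is not None else "",
                "flag": profile.flag or "",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# -- taxonomy ---------------------------------------------------------------

def write_taxonomy_tsv(profiles: Mapping[str, TaxonomyProfile], path: str | Path) -> None:
    rows = []
    for cid in sorted(profiles):
        p = profiles[cid]
        row = {
            "contig": cid,
            "n_genes": p.n_genes,
            "n_genes_with_hits": p.n_genes_with_hits,
            "domain_call": p.domain_call,
            "top_genus": p.top_genus or "",
            "top_genus_gene_count": p.top_genus_gene_count,
            "runner_up_genus_gene_count": p.runner_up_genus_gene_count,
        }
        for rank in RANKS:
            call = p.calls.get(rank)
            row[f"{rank}_call"] = call[0] if call else "no_call"
            row[f"{rank}_fraction"] = round(call[1], 4) if call else ""
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# -- screen -----------------------------------------------------------------

def write_screen_tsv(results: Sequence[BorgCriteriaResult], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "contig": r.contig_id,
                "c1_ref_alignment": r.c1_ref_alignment,
                "c2_no_domain": r.c2_no_domain,
                "c3_gc_in_range": r.c3_gc_in_range,
                "c4_repeat_arrays": r.c4_repeat_arrays,
                "c5_genus_dominance": r.c5_genus_dominance,
                "n_other_criteria_met": r.n_other_criteria_met,
                "classification": r.classification,
            }
            for r in results
        ]
    ).to_csv(path, sep="\t", index=False)


def write_bins_tsv(bins: Sequence[Bin], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "bin": b.bin_id,
                "members": ",".join(b.members),
                "coverage_centroid": round(b.coverage_centroid, 3),
                "gc_centroid": round(b.gc_centroid, 4),
            }
            for b in bins
        ]
    ).to_csv(path, sep="\t", index=False)


def write_joins_tsv(joins: Sequence[Join], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "a": j.a_id,
                "a_strand": j.a_strand,
                "b": j.b_id,
                "b_strand": j.b_strand,
                "overlap": j.overlap,
            }
            for j in joins
        ]
    ).to_csv(path, sep="\t", index=False)


# -- host linkage -----------------------------------------------------------

def write_associations_tsv(associations: Sequence[HostAssociation], path: str | Path) -> None:
    associations_to_frame(associations).to_csv(path, sep="\t", index=False)


# -- motifs / spacers -------------------------------------------------------

def write_mhc_tsv(reports: Sequence[MotifReport], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "protein": r.protein_id,
                "n_cxxch": r.n_cxxch,
                "positions": ",".join(map(str, r.positions)),
                "is_mhc": r.is_mhc,
            }
            for r in reports
        ]
    ).to_csv(path, sep="\t", index=False)


def write_spacer_hits_tsv(matches: Sequence[SpacerMatch], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "spacer": m.spacer_id,
                "array": m.array_id,
                "target": m.target_id,
                "target_start": m.target_start + 1,
                "strand": m.strand,
                "align_length": m.align_length,
                "mismatches": m.mismatches,
                "tier": m.tier,
            }
            for m in matches
        ]
    ).to_csv(path, sep="\t", index=False)
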