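"""Synthetic communities of Borg-like elements with planted ground truth.

Real discovery of giant linear extrachromosomal elements starts from raw
metagenomes that cannot ship with a package.  This module generates, from a
seed, the downstream artifacts of such a study — contigs, gene tables with
best-hit taxonomy, protein sequences and a sample x element count matrix —
with every screening feature planted and recorded, so the whole pipeline can
be exercised against known truth.

A simulated Borg genome is linear, ~0.6-1 Mb, terminated by >= 1 kb perfect
inverted repeats, carries dozens of perfect tandem direct-repeat arrays
(aperiodic units, flanked by blocker bases so copy number is unambiguous),
has two replichores meeting at a planted terminus with opposite GC skew and
near-complete strand segregation of genes, a ~33% GC baseline with a handful
of elevated-GC gene islands, mostly hit-less gene annotations whose hit
plurality is *Methanoperedens*, and a per-sample abundance tied to its host's
at a fixed copy ratio.  Host contigs sit ~10 GC points higher with a clear
archaeal voting profile; background contigs get unrelated taxonomy and
independent abundances.

Base composition is i.i.d. per position at the local target GC/skew outside
planted features; counts are negative binomial around the expected depth.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import LinearGenome, decode, gc_fraction, revcomp_codes
from .motif_crispr import Spacer
from .repeat_scan import _minimal_period


class PackingError(ValueError):
    """Requested planted features do not fit in the genome."""


# ---------------------------------------------------------------------------
# specifications

@dataclass
class BorgSpec:
    """Parameters of one simulated Borg-like genome."""

    genome_length: int = 800_000
    itr_length: int = 1_500
    gc_baseline: float = 0.33
    n_repeat_arrays: int = 35
    repeat_unit_len_range: tuple[int, int] = (20, 60)
    repeat_copies_range: tuple[int, int] = (3, 8)
    replichore_split: float = 0.6
    strand_fidelity: float = 0.97
    n_elevated_gc_genes: int = 12
    elevated_gc_delta: float = 10.0  # percentage points above baseline
    host_index: int = 0
    copy_ratio_range: tuple[float, float] = (2.0, 8.0)
    skew_strength: float = 0.10  # G excess among G+C on the leading strand
    n_mhc_genes: int = 16
    name: str | None = None

    def validate(self) -> None:
        if not 0.0 < self.replichore_split < 1.0:
            raise ValueError("replichore_split must be in (0, 1)")
        if self.itr_length < 1_000:
            raise ValueError("itr_length must be >= 1000 bp to emulate complete genomes")
        if not 0.0 < self.gc_baseline < 1.0:
            raise ValueError("gc_baseline must be a fraction")
        if self.repeat_copies_range[0] < 2:
            raise ValueError("repeat arrays need >= 2 copies")


@dataclass
class HostSpec:
    """Parameters of one simulated host genome (a single large contig)."""

    genome_length: int = 150_000
    gc: float = 0.43
    mean_depth_range: tuple[float, float] = (10.0, 40.0)
    name: str | None = None


@dataclass
class SimConfig:
    """Full community simulation configuration."""

    seed: int = 42
    n_samples: int = 50
    borg_specs: list[BorgSpec] = field(default_factory=lambda: [BorgSpec()])
    host_specs: list[HostSpec] = field(default_factory=lambda: [HostSpec()])
    n_background_contigs: int = 20
    noise_cv: float = 0.05
    background_length_range: tuple[int, int] = (8_000, 40_000)
    background_gc_range: tuple[float, float] = (0.36, 0.65)
    read_length: int = 150
    depth_lognorm_sigma: float = 0.9  # sample-to-sample spread of host depth


def default_community_config(seed: int = 42) -> SimConfig:
    """The reference study conditions: four Borg-like genomes spanning the
    complete-genome size range, two host populations (two Borgs tracking
    each), twenty background contigs and fifty samples."""
    borg_lengths = (661_708, 740_000, 830_000, 918_293)
    n_arrays = (25, 35, 45, 54)
    itrs = (1_500, 1_800, 2_200, 2_600)
    splits = (0.60, 0.55, 0.65, 0.58)
    hosts = (0, 0, 1, 1)
    borgs = [
        BorgSpec(
            genome_length=L,
            itr_length=itr,
            n_repeat_arrays=na,
            replichore_split=sp,
            host_index=h,
            n_elevated_gc_genes=12 + 2 * i,
            name=f"borg_{i + 1}",
        )
        for i, (L, itr, na, sp, h) in enumerate(
            zip(borg_lengths, itrs, n_arrays, splits, hosts)
        )
    ]
    hosts_specs = [
        HostSpec(genome_length=150_000, mean_depth_range=(10.0, 40.0), name="host_1"),
        HostSpec(genome_length=180_000, mean_depth_range=(8.0, 30.0), name="host_2"),
    ]
    return SimConfig(seed=seed, borg_specs=borgs, host_specs=hosts_specs)


# ---------------------------------------------------------------------------
# taxonomy label pools (7-rank semicolon paths)

METHANOPEREDENS_PATH = (
    "Archaea;Halobacterota;Methanosarcinia;Methanosarcinales;"
    "Methanoperedenaceae;Methanoperedens;Methanoperedens sp."
)
_OTHER_ARCHAEA = [
    "Archaea;Halobacterota;Methanosarcinia;Methanosarcinales;Methanosarcinaceae;Methanosarcina;Methanosarcina mazei",
    "Archaea;Euryarchaeota;Methanobacteria;Methanobacteriales;Methanobacteriaceae;Methanobacterium;Methanobacterium formicicum",
    "Archaea;Thermoproteota;Nitrososphaeria;Nitrososphaerales;Nitrososphaeraceae;Nitrososphaera;Nitrososphaera viennensis",
    "Archaea;Euryarchaeota;Methanomicrobia;Methanomicrobiales;Methanoregulaceae;Methanoregula;Methanoregula boonei",
    "Archaea;Euryarchaeota;Archaeoglobi;Archaeoglobales;Archaeoglobaceae;Archaeoglobus;Archaeoglobus fulgidus",
    "Archaea;Euryarchaeota;Thermococci;Thermococcales;Thermococcaceae;Thermococcus;Thermococcus kodakarensis",
]
_BACTERIA = [
    "Bacteria;Nitrospirota;Nitrospiria;Nitrospirales;Nitrospiraceae;Nitrospira;Nitrospira defluvii",
    "Bacteria;Pseudomonadota;Gammaproteobacteria;Pseudomonadales;Pseudomonadaceae;Pseudomonas;Pseudomonas fluorescens",
    "Bacteria;Bacillota;Clostridia;Eubacteriales;Clostridiaceae;Clostridium;Clostridium butyricum",
    "Bacteria;Actinomycetota;Actinomycetes;Mycobacteriales;Mycobacteriaceae;Mycobacterium;Mycobacterium smegmatis",
    "Bacteria;Desulfobacterota;Desulfovibrionia;Desulfovibrionales;Desulfovibrionaceae;Desulfovibrio;Desulfovibrio vulgaris",
    "Bacteria;Chloroflexota;Anaerolineae;Anaerolineales;Anaerolineaceae;Anaerolinea;Anaerolinea thermophila",
    "Bacteria;Acidobacteriota;Acidobacteriia;Acidobacteriales;Acidobacteriaceae;Acidobacterium;Acidobacterium capsulatum",
    "Bacteria;Bacteroidota;Bacteroidia;Bacteroidales;Bacteroidaceae;Bacteroides;Bacteroides fragilis",
]

_AA = np.frombuffer(b"ACDEFGHIKLMNPQRSTVWY", dtype=np.uint8)
_AA_NO_CH = np.frombuffer(b"ADEFGIKLMNPQRSTVWY", dtype=np.uint8)


# ---------------------------------------------------------------------------
# low-level draws

def _draw_codes(rng: np.random.Generator, n: int, gc: float, skew: float = 0.0) -> np.ndarray:
    """i.i.d. base codes at target GC; ``skew`` is the G excess among G+C."""
    p_g = gc * (1.0 + skew) / 2.0
    p_c = gc * (1.0 - skew) / 2.0
    p_a = p_t = (1.0 - gc) / 2.0
    cuts = np.cumsum([p_a, p_c, p_g, p_t])
    return np.searchsorted(cuts[:3], rng.random(n), side="right").astype(np.uint8)


def _other_code(rng: np.random.Generator, *avoid: int) -> int:
    choices = [c for c in range(4) if c not in avoid]
    return int(choices[rng.integers(len(choices))])


# ---------------------------------------------------------------------------
# single-genome simulation

def simulate_borg_genome(
    spec: BorgSpec,
    rng: np.random.Generator,
    genome_id: str = "borg_1",
) -> tuple[LinearGenome, pd.DataFrame, dict]:
    """Simulate one Borg-like linear genome with planted features.

    Returns the genome, its gene table (0-based half-open ``start``/``end``,
    ``strand``, ``gc_class``) and a truth slice recording the planted ITR,
    arrays, terminus and elevated-GC genes.  Raises :class:`PackingError`
    when the requested arrays plus ITRs do not fit.
    """
    spec.validate()
    L = spec.genome_length
    itr = spec.itr_length
    s = spec.skew_strength
    T = int(round(spec.replichore_split * L))

    # draw array geometries up front to check packing feasibility
    unit_lens = rng.integers(
        spec.repeat_unit_len_range[0], spec.repeat_unit_len_range[1] + 1, spec.n_repeat_arrays
    )
    copy_nums = rng.integers(
        spec.repeat_copies_range[0], spec.repeat_copies_range[1] + 1, spec.n_repeat_arrays
    )
    spans = unit_lens * copy_nums
    margin = 10
    interior = L - 2 * (itr + margin)
    if spans.sum() + 2 * margin * max(1, spec.n_repeat_arrays) > max(interior, 0):
        raise PackingError(
            f"{spec.n_repeat_arrays} arrays totalling {int(spans.sum())} bp plus two "
            f"{itr} bp terminal repeats do not fit in {L} bp"
        )

    # baseline sequence: two replichores with opposite GC skew meeting at T
    codes = np.empty(L, dtype=np.uint8)
    codes[:T] = _draw_codes(rng, T, spec.gc_baseline, +s)
    codes[T:] = _draw_codes(rng, L - T, spec.gc_baseline, -s)

    # plant tandem arrays (aperiodic units, blocker base each side)
    occupied: list[tuple[int, int]] = []
    arrays_truth: list[dict] = []
    for ulen, cnum in zip(unit_lens, copy_nums):
        ulen, cnum = int(ulen), int(cnum)
        span = ulen * cnum
        hi_limit = L - itr - margin - span
        if hi_limit <= itr + margin:
            raise PackingError("array span exceeds the genome interior")
        placed = False
        for _try in range(2_000):
            start = int(rng.integers(itr + margin, hi_limit))
            lo, hi = start - margin, start + span + margin
            if all(hi <= a or lo >= b for a, b in occupied):
                placed = True
                break
        if not placed:
            raise PackingError("could not place a repeat array without overlap")
        local_skew = +s if start < T else -s
        for _try in range(200):
            unit = _draw_codes(rng, ulen, spec.gc_baseline, local_skew)
            if _minimal_period(unit.tobytes()) == ulen:
                break
        else:  # pragma: no cover - vanishingly unlikely
            raise PackingError("failed to draw an aperiodic repeat unit")
        end = start + span
        codes[start:end] = np.tile(unit, cnum)
        # blockers: the array must not extend by a full or partial unit
        if codes[start - 1] == unit[-1]:
            codes[start - 1] = _other_code(rng, int(unit[-1]))
        if codes[end] == unit[0]:
            codes[end] = _other_code(rng, int(unit[0]))
        occupied.append((start - 1, end + 1))
        arrays_truth.append(
            {
                "start": start,
                "end": end,
                "unit_seq": decode(unit),
                "unit_len": ulen,
                "copies": cnum,
            }
        )
    arrays_truth.sort(key=lambda a: a["start"])

    # terminal inverted repeat: right end is the reverse complement of the
    # left end; a blocker just inside keeps the ITR at its exact length
    codes[L - itr :] = revcomp_codes(codes[:itr])
    if codes[itr] == 3 - codes[L - itr - 1]:
        codes[itr] = _other_code(rng, int(codes[itr]))

    # gene tiling with per-replichore majority strand
    gene_rows = []
    pos = itr + int(rng.integers(50, 151))
    i_gene = 0
    while True:
        glen = int(rng.integers(600, 1_501))
        if pos + glen > L - itr:
            break
        mid = pos + glen // 2
        major = "+" if mid < T else "-"
        minor = "-" if major == "+" else "+"
        strand = major if rng.random() < spec.strand_fidelity else minor
        gene_rows.append(
            {
                "contig": genome_id,
                "gene_id": f"{genome_id}_g{i_gene + 1:04d}",
                "start": pos,
                "end": pos + glen,
                "strand": strand,
            }
        )
        i_gene += 1
        pos += glen + int(rng.integers(50, 151))
    genes = pd.DataFrame(gene_rows)

    # elevated-GC gene islands (recent lateral acquisitions); rewrite genes
    # that do not touch planted arrays or the terminal repeats
    gc_class = np.array(["baseline"] * len(genes), dtype=object)
    candidates = []
    for i, row in genes.iterrows():
        gs, ge = int(row["start"]), int(row["end"])
        if any(ge > a and gs < b for a, b in occupied):
            continue
        candidates.append(i)
    if spec.n_elevated_gc_genes > len(candidates):
        raise PackingError("not enough array-free genes for the requested GC islands")
    if spec.n_elevated_gc_genes:
        chosen = rng.choice(len(candidates), size=spec.n_elevated_gc_genes, replace=False)
        for ci in sorted(int(c) for c in chosen):
            i = candidates[ci]
            gs, ge = int(genes.at[i, "start"]), int(genes.at[i, "end"])
            local_skew = +s if (gs + ge) // 2 < T else -s
            codes[gs:ge] = _draw_codes(
                rng, ge - gs, spec.gc_baseline + spec.elevated_gc_delta / 100.0, local_skew
            )
            gc_class[i] = "elevated"
    genes["gc_class"] = gc_class

    genome = LinearGenome(id=genome_id, seq=decode(codes), topology="linear", source="simulated")
    truth = {
        "genome_id": genome_id,
        "length": L,
        "itr_length": itr,
        "itr_left": [0, itr],
        "itr_right": [L - itr, L],
        "terminus": T,
        "origin": [0, L],
        "arrays": arrays_truth,
        "elevated_genes": genes.loc[gc_class == "elevated", "gene_id"].tolist(),
        "gc_baseline": spec.gc_baseline,
    }
    return genome, genes, truth


def _tile_genes(
    rng: np.random.Generator, contig_id: str, length: int, start0: int = 0
) -> pd.DataFrame:
    rows = []
    pos = start0 + int(rng.integers(20, 120))
    i = 0
    while True:
        glen = int(rng.integers(600, 1_501))
        if pos + glen > length:
            break
        rows.append(
            {
                "contig": contig_id,
                "gene_id": f"{contig_id}_g{i + 1:04d}",
                "start": pos,
                "end": pos + glen,
                "strand": "+" if rng.random() < 0.5 else "-",
                "gc_class": "baseline",
            }
        )
        i += 1
        pos += glen + int(rng.integers(50, 151))
    return pd.DataFrame(rows)


def _assign_borg_hits(rng: np.random.Generator, n: int) -> list[str]:
    """Best-hit paths for Borg genes: mostly no hit, hit plurality is
    Methanoperedens, no rank anywhere near a strict majority."""
    hits = []
    for _ in range(n):
        u = rng.random()
        if u < 0.70:
            hits.append("none")
        elif u < 0.85:
            hits.append(METHANOPEREDENS_PATH)
        elif u < 0.95:
            hits.append(_OTHER_ARCHAEA[int(rng.integers(len(_OTHER_ARCHAEA)))])
        else:
            hits.append(_BACTERIA[int(rng.integers(len(_BACTERIA)))])
    return hits


def _assign_host_hits(rng: np.random.Generator, n: int) -> list[str]:
    hits = []
    for _ in range(n):
        u = rng.random()
        if u < 0.80:
            hits.append(METHANOPEREDENS_PATH)
        elif u < 0.90:
            hits.append(_OTHER_ARCHAEA[int(rng.integers(len(_OTHER_ARCHAEA)))])
        else:
            hits.append("none")
    return hits


def _assign_background_hits(rng: np.random.Generator, n: int) -> list[str]:
    dominant = _BACTERIA[int(rng.integers(len(_BACTERIA)))]
    hit_frac = rng.uniform(0.3, 0.9)
    hits = []
    for _ in range(n):
        if rng.random() >= hit_frac:
            hits.append("none")
        elif rng.random() < 0.7:
            hits.append(dominant)
        else:
            hits.append(_BACTERIA[int(rng.integers(len(_BACTERIA)))])
    return hits


def _random_protein(rng: np.random.Generator, length: int) -> np.ndarray:
    return _AA[rng.integers(0, len(_AA), size=length)]


def _mhc_protein(rng: np.random.Generator, length: int, n_motifs: int) -> np.ndarray:
    """A protein with exactly ``n_motifs`` CxxCH motifs.

    The backbone uses no C or H at all, so the planted motifs are the only
    ones present and the planted count is exact.
    """
    length = max(length, 6 * n_motifs + 10)
    prot = _AA_NO_CH[rng.integers(0, len(_AA_NO_CH), size=length)]
    slot = length // n_motifs
    for m in range(n_motifs):
        p = m * slot + int(rng.integers(0, max(1, slot - 6)))
        prot[p] = ord("C")
        prot[p + 3] = ord("C")
        prot[p + 4] = ord("H")
    return prot


# ---------------------------------------------------------------------------
# community simulation

@dataclass
class SimTruth:
    """Everything planted by :func:`simulate_community`."""

    genomes: dict = field(default_factory=dict)  # genome_id -> truth slice
    host_of: dict = field(default_factory=dict)  # borg_id -> host_id
    true_ratio: dict = field(default_factory=dict)  # borg_id -> copy ratio
    host_mean_depth: dict = field(default_factory=dict)
    mhc_proteins: dict = field(default_factory=dict)  # protein_id -> planted motif count
    background_ids: list = field(default_factory=list)
    borg_ids: list = field(default_factory=list)
    host_ids: list = field(default_factory=list)


@dataclass
class Community:
    """In-memory result of a community simulation."""

    config: SimConfig
    contigs: list[LinearGenome]
    genes: pd.DataFrame
    proteins: dict
    counts: pd.DataFrame
    lengths: pd.Series
    truth: SimTruth

    def contig(self, contig_id: str) -> LinearGenome:
        return next(c for c in self.contigs if c.id == contig_id)


def simulate_community(cfg: SimConfig) -> Community:
    """Simulate a full community with planted truth (deterministic per seed)."""
    if cfg.n_samples < 2:
        raise ValueError("n_samples must be >= 2 (correlation is undefined otherwise)")
    rng = np.random.default_rng(cfg.seed)
    truth = SimTruth()
    contigs: list[LinearGenome] = []
    gene_frames: list[pd.DataFrame] = []
    proteins: dict[str, str] = {}

    host_ids = []
    for i, hspec in enumerate(cfg.host_specs):
        hid = hspec.name or f"host_{i + 1}"
        host_ids.append(hid)
        codes = _draw_codes(rng, hspec.genome_length, hspec.gc)
        contigs.append(LinearGenome(id=hid, seq=decode(codes), source="simulated"))
        genes = _tile_genes(rng, hid, hspec.genome_length)
        genes["best_hit_taxonomy"] = _assign_host_hits(rng, len(genes))
        gene_frames.append(genes)
    truth.host_ids = host_ids

    borg_ids = []
    for i, bspec in enumerate(cfg.borg_specs):
        bid = bspec.name or f"borg_{i + 1}"
        borg_ids.append(bid)
        genome, genes, slice_truth = simulate_borg_genome(bspec, rng, genome_id=bid)
        genes["best_hit_taxonomy"] = _assign_borg_hits(rng, len(genes))
        contigs.append(genome)
        gene_frames.append(genes)
        truth.genomes[bid] = slice_truth
        truth.host_of[bid] = host_ids[bspec.host_index]
        # MHC-bearing genes
        if bspec.n_mhc_genes:
            mhc_idx = rng.choice(len(genes), size=bspec.n_mhc_genes, replace=False)
            mhc_set = {int(k) for k in mhc_idx}
        else:
            mhc_set = set()
        for j, row in genes.iterrows():
            plen = max(60, (int(row["end"]) - int(row["start"])) // 3 - 1)
            if j in mhc_set:
                n_motifs = int(rng.integers(3, 33))
                prot = _mhc_protein(rng, plen, n_motifs)
                truth.mhc_proteins[row["gene_id"]] = n_motifs
            else:
                prot = _random_protein(rng, plen)
            proteins[row["gene_id"]] = prot.tobytes().decode("ascii")

    for i in range(cfg.n_background_contigs):
        cid = f"bg_{i + 1:03d}"
        truth.background_ids.append(cid)
        blen = int(rng.integers(*cfg.background_length_range))
        bgc = float(rng.uniform(*cfg.background_gc_range))
        codes = _draw_codes(rng, blen, bgc)
        contigs.append(LinearGenome(id=cid, seq=decode(codes), source="simulated"))
        genes = _tile_genes(rng, cid, blen)
        genes["best_hit_taxonomy"] = _assign_background_hits(rng, len(genes))
        gene_frames.append(genes)
    truth.borg_ids = borg_ids

    # proteins for non-Borg contigs (host + background): random sequences
    all_genes = pd.concat(gene_frames, ignore_index=True)
    for _, row in all_genes.iterrows():
        gid = row["gene_id"]
        if gid not in proteins:
            plen = max(60, (int(row["end"]) - int(row["start"])) // 3 - 1)
            proteins[gid] = _random_protein(rng, plen).tobytes().decode("ascii")

    # abundance matrix
    sample_ids = [f"sample_{k + 1:02d}" for k in range(cfg.n_samples)]
    lengths = pd.Series({c.id: len(c.seq) for c in contigs}, name="length")
    depth = {}
    for i, hspec in enumerate(cfg.host_specs):
        mu = float(rng.uniform(*hspec.mean_depth_range))
        truth.host_mean_depth[host_ids[i]] = mu
        depth[host_ids[i]] = mu * rng.lognormal(0.0, cfg.depth_lognorm_sigma, cfg.n_samples)
    for i, bspec in enumerate(cfg.borg_specs):
        bid = borg_ids[i]
        ratio = float(rng.uniform(*bspec.copy_ratio_range))
        truth.true_ratio[bid] = ratio
        depth[bid] = ratio * depth[truth.host_of[bid]]
    for cid in truth.background_ids:
        mu = float(rng.uniform(1.0, 30.0))
        depth[cid] = mu * rng.lognormal(0.0, cfg.depth_lognorm_sigma, cfg.n_samples)

    counts = np.zeros((len(contigs), cfg.n_samples), dtype=np.int64)
    for r, c in enumerate(contigs):
        mean = depth[c.id] * lengths[c.id] / cfg.read_length
        counts[r] = _noisy_counts(rng, mean, cfg.noise_cv)
    counts_df = pd.DataFrame(counts, index=[c.id for c in contigs], columns=sample_ids)

    return Community(
        config=cfg,
        contigs=contigs,
        genes=all_genes,
        proteins=proteins,
        counts=counts_df,
        lengths=lengths,
        truth=truth,
    )


def _noisy_counts(rng: np.random.Generator, mean: np.ndarray, cv: float) -> np.ndarray:
    """Negative-binomial counts with coefficient of variation ``cv`` (Poisson
    where the requested variance would undershoot the Poisson floor)."""
    out = np.empty(len(mean), dtype=np.int64)
    for k, mu in enumerate(mean):
        if mu <= 0:
            out[k] = 0
            continue
        var = (cv * mu) ** 2
        if var <= mu:
            out[k] = rng.poisson(mu)
        else:
            r = mu * mu / (var - mu)
            p = r / (r + mu)
            out[k] = rng.negative_binomial(r, p)
    return out


def simulate_background_contigs(
    rng: np.random.Generator,
    n: int,
    length_range: tuple[int, int] = (8_000, 40_000),
    gc_range: tuple[float, float] = (0.36, 0.65),
    prefix: str = "bg",
) -> tuple[list[LinearGenome], pd.DataFrame]:
    """Background (non-Borg, non-host) contigs with gene tables only.

    A light-weight generator for large null calibrations where abundance
    profiles are not needed.
    """
    contigs: list[LinearGenome] = []
    frames: list[pd.DataFrame] = []
    for i in range(n):
        cid = f"{prefix}_{i + 1:04d}"
        blen = int(rng.integers(*length_range))
        bgc = float(rng.uniform(*gc_range))
        contigs.append(
            LinearGenome(id=cid, seq=decode(_draw_codes(rng, blen, bgc)), source="simulated")
        )
        genes = _tile_genes(rng, cid, blen)
        genes["best_hit_taxonomy"] = _assign_background_hits(rng, len(genes))
        frames.append(genes)
    return contigs, pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# CRISPR spacer simulation (inputs for the spacer-matching stage)

def simulate_spacer_set(
    rng: np.random.Generator,
    target: LinearGenome,
    n_arrays: int = 3,
    spacers_per_array: int = 4,
    spacer_len_range: tuple[int, int] = (28, 38),
) -> tuple[list[Spacer], list[dict]]:
    """Sample CRISPR spacers from a target with planted mismatch structure.

    Each simulated array gets one exact protospacer (a primary anchor), plus
    siblings carrying 0-3 mismatches; a final decoy array carries only 2-3
    mismatch spacers (which the two-tier rule must drop).  Returns the spacer
    list and a truth record of planted mismatch counts.
    """
    seq = target.seq.upper()
    L = len(seq)
    spacers: list[Spacer] = []
    truth: list[dict] = []
    sid = 0
    for a in range(n_arrays):
        array_id = f"array_{a + 1}"
        for k in range(spacers_per_array):
            slen = int(rng.integers(*spacer_len_range))
            start = int(rng.integers(0, L - slen))
            s = list(seq[start : start + slen])
            mm = 0 if k == 0 else int(rng.integers(0, 4))
            pos = rng.choice(slen, size=mm, replace=False)
            for p in pos:
                cur = s[int(p)]
                s[int(p)] = "ACGT"[("ACGT".index(cur) + 1 + int(rng.integers(3))) % 4]
            sid += 1
            spacers.append(Spacer(f"sp_{sid:03d}", array_id, "".join(s)))
            truth.append(
                {"spacer_id": f"sp_{sid:03d}", "array_id": array_id,
                 "target_start": start, "mismatches": mm}
            )
    # decoy array: no primary anchor
    array_id = f"array_{n_arrays + 1}"
    for k in range(2):
        slen = int(rng.integers(*spacer_len_range))
        start = int(rng.integers(0, L - slen))
        s = list(seq[start : start + slen])
        mm = 2 + k  # 2 then 3 mismatches, never a primary
        pos = rng.choice(slen, size=mm, replace=False)
        for p in pos:
            cur = s[int(p)]
            s[int(p)] = "ACGT"[("ACGT".index(cur) + 1 + int(rng.integers(3))) % 4]
        sid += 1
        spacers.append(Spacer(f"sp_{sid:03d}", array_id, "".join(s)))
        truth.append(
            {"spacer_id": f"sp_{sid:03d}", "array_id": array_id,
             "target_start": start, "mismatches": mm}
        )
    return spacers, truth


# ---------------------------------------------------------------------------
# fragmentation helper (binning / end-overlap tests)

def fragment_genome(
    genome: LinearGenome, n_fragments: int, overlap: int = 120
) -> list[LinearGenome]:
    """Split a genome into ``n_fragments`` consecutive pieces whose ends
    overlap perfectly by ``overlap`` bp (emulating a fragmented assembly)."""
    L = len(genome.seq)
    if n_fragments < 2 or overlap >= L // n_fragments:
        raise ValueError("infeasible fragmentation")
    cuts = np.linspace(0, L, n_fragments + 1, dtype=int)
    out = []
    for i in range(n_fragments):
        a = int(cuts[i])
        b = min(L, int(cuts[i + 1]) + (overlap if i < n_fragments - 1 else 0))
        out.append(
            LinearGenome(
                id=f"{genome.id}_frag{i + 1}", seq=genome.seq[a:b], source="fragment"
            )
        )
    return out


# ---------------------------------------------------------------------------
# file emission

def write_community(comm: Community, outdir: str | Path) -> dict[str, Path]:
    """Write contigs.fasta, proteins.faa, genes.tsv (1-based inclusive),
    counts.tsv, lengths.tsv and truth.json; byte-identical per config."""
    from . import io as bio  # local import to avoid a cycle

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "contigs": outdir / "contigs.fasta",
        "proteins": outdir / "proteins.faa",
        "genes": outdir / "genes.tsv",
        "counts": outdir / "counts.tsv",
        "lengths": outdir / "lengths.tsv",
        "truth": outdir / "truth.json",
    }
    bio.write_fasta(comm.contigs, paths["contigs"])
    bio.write_protein_fasta(comm.proteins, paths["proteins"])
    bio.write_genes_tsv(comm.genes, paths["genes"])
    comm.counts.to_csv(paths["counts"], sep="\t", index_label="element")
    comm.lengths.to_frame().to_csv(paths["lengths"], sep="\t", index_label="element")
    with open(paths["truth"], "w") as fh:
        json.dump(dataclasses.asdict(comm.truth), fh, indent=1, default=_jsonable)
        fh.write("\n")
    return paths


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def load_truth(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
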