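"""Synthetic rRNA alignments, trees and ground-truth records.

The generator emulates the data regime the pipeline is designed for:
multi-species ITS+LSU alignments with tight intraspecific clusters,
larger interspecific divergence, occasional ambiguity codes and indel
runs, and optionally a planted 20-30 base diagnostic motif whose
separation from all other species is guaranteed by construction.

Sequences evolve under JC69 along a Yule (pure-birth) species tree whose
depth is scaled so that realized divergences hit the configured targets;
conspecific sequences hang off each species tip as a star with pairwise
path length matched to the within-species target. Branch-wise, the
per-site substitution probability is p(t) = (3/4)(1 - exp(-4t/3)).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import numpy as np

from . import iupac
from .alignment import (
    AlignedSequence,
    Alignment,
    RegionMap,
    read_alignment,
    write_alignment,
    write_taxon_map,
)
from .delimitation import PhyloTree

_BASES = np.array([ord(b) for b in "ACGT"], dtype=np.uint8)
#: two-base ambiguity code containing each pure base (plus N), by base index
_AMBIG_FOR = {0: "RWM", 1: "YSM", 2: "RSK", 3: "YWK"}

DEFAULT_REGION_LENGTHS = {"ITS1": 150, "5.8S": 155, "ITS2": 200, "LSU": 700}


def jc69_p(t: float) -> float:
    """Expected per-site difference after total branch length *t*."""
    return 0.75 * (1.0 - np.exp(-4.0 * t / 3.0))


def jc69_t(p: float) -> float:
    """Branch length at which the expected per-site difference is *p*."""
    if not 0 <= p < 0.75:
        raise ValueError("p must be in [0, 0.75) under JC69")
    return -0.75 * np.log(1.0 - 4.0 * p / 3.0)


@dataclass
class PlantedBarcodeSpec:
    length: int = 25
    min_separation: int = 3
    region: str = "ITS2"
    target_species: str | None = None   # default: first species


@dataclass
class SimulationConfig:
    n_species: int = 10
    seqs_per_species: int = 5
    region_lengths: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_REGION_LENGTHS))
    within_divergence: float = 0.01
    between_divergence: float = 0.08
    n_genera: int | None = None
    between_genus_divergence: float = 0.15
    indel_rate: float = 0.0005          # per site: probability a gap run starts
    indel_mean_length: float = 5.0
    ambiguity_rate: float = 0.001       # per site, per sequence
    planted: PlantedBarcodeSpec | None = None
    model: str = "JC69"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if not 0 <= self.within_divergence < self.between_divergence < 1:
            raise ValueError("need 0 <= within < between < 1")
        if self.model != "JC69":
            raise ValueError(f"unimplemented substitution model {self.model!r}")

    @property
    def n_columns(self) -> int:
        return sum(self.region_lengths.values())

    def region_map(self) -> RegionMap:
        entries, start = {}, 1
        for name, length in self.region_lengths.items():
            entries[name] = (start, start + length - 1)
            start += length
        entries["full"] = (1, start - 1)
        return RegionMap(entries, start - 1)


@dataclass
class PlantedTruth:
    region: str
    window_columns: tuple[int, int]     # 1-based inclusive alignment columns
    positions: tuple[int, int]          # region-relative (gap-free window)
    barcode: str
    target_species: str
    expected_d_out: int


@dataclass
class SyntheticTruth:
    species_of: dict[str, str]
    genus_of: dict[str, str]
    max_within_divergence: dict[str, float]
    newick: str
    planted: PlantedTruth | None = None

    def to_json(self) -> str:
        d = {
            "species_of": self.species_of,
            "genus_of": self.genus_of,
            "max_within_divergence": self.max_within_divergence,
            "newick": self.newick,
            "planted": asdict(self.planted) if self.planted else None,
        }
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        d = json.loads(text)
        planted = d["planted"]
        return cls(
            species_of=d["species_of"],
            genus_of=d["genus_of"],
            max_within_divergence=d["max_within_divergence"],
            newick=d["newick"],
            planted=PlantedTruth(
                region=planted["region"],
                window_columns=tuple(planted["window_columns"]),
                positions=tuple(planted["positions"]),
                barcode=planted["barcode"],
                target_species=planted["target_species"],
                expected_d_out=planted["expected_d_out"],
            ) if planted else None,
        )


# ---------------------------------------------------------------------------
# Trees

def _yule_shape(n_tips: int, rng: np.random.Generator) -> dendropy.Tree:
    """Unit-rate Yule tree on *n_tips* unnamed leaves."""
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    tips = [tree.seed_node]
    if n_tips == 1:
        tree.seed_node.edge.length = 0.0
        return tree
    t = 0.0
    events = []
    while len(tips) < n_tips:
        t += rng.exponential(1.0 / len(tips))
        victim = tips.pop(rng.integers(len(tips)))
        victim.birth_time = t
        for _ in range(2):
            child = victim.new_child()
            tips.append(child)
        events.append(t)
    t_end = t + rng.exponential(1.0 / len(tips))
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            node.edge.length = 0.0
            continue
        parent_t = getattr(node.parent_node, "birth_time", 0.0)
        node_t = getattr(node, "birth_time", t_end)
        node.edge.length = node_t - parent_t
    return tree


def _mean_pairwise_depth(tree: dendropy.Tree) -> float:
    """Mean tip-to-tip path length."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = list(tree.taxon_namespace)
    if len(taxa) < 2:
        return 0.0
    ds = [pdm.patristic_distance(a, b)
          for i, a in enumerate(taxa) for b in taxa[i + 1:]]
    return float(np.mean(ds))


def _scale_to_mean_pairwise(tree: dendropy.Tree, target: float) -> None:
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is None:
            leaf.taxon = tree.taxon_namespace.new_taxon(f"tmp{id(leaf)}")
    mean = _mean_pairwise_depth(tree)
    if mean > 0:
        factor = target / mean
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= factor


def simulate_tree(config: SimulationConfig) -> PhyloTree:
    """Species tree with conspecific tips, deterministic per seed.

    The species-level Yule tree is rescaled so the mean pairwise
    species-to-species path equals the JC69 branch length matching the
    between-species divergence target; each species tip carries a star of
    ``seqs_per_species`` sequence tips with pairwise path matched to the
    within-species target. With ``n_genera`` set, a genus-level Yule tree
    is built first and species trees are grafted onto its tips.
    """
    rng = np.random.default_rng(config.seed)
    t_within = jc69_t(config.within_divergence)
    t_between = jc69_t(config.between_divergence)

    if config.n_genera:
        top = _yule_shape(config.n_genera, rng)
        _scale_to_mean_pairwise(top, jc69_t(config.between_genus_divergence))
        genus_tips = list(top.leaf_node_iter())
        per = int(np.ceil(config.n_species / config.n_genera))
        sp_counter = 0
        for g, tip in enumerate(genus_tips):
            k = min(per, config.n_species - sp_counter)
            sub = _yule_shape(max(k, 1), rng)
            _scale_to_mean_pairwise(sub, t_between)
            _graft(tip, sub)
            for leaf in tip.leaf_iter():
                sp_counter += 1
                leaf.species_name = f"sp{sp_counter:02d}"
                leaf.genus_name = f"gen{g + 1:02d}"
        tree = top
    else:
        tree = _yule_shape(config.n_species, rng)
        _scale_to_mean_pairwise(tree, t_between)
        for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
            leaf.species_name = f"sp{i:02d}"
            leaf.genus_name = "gen01"

    # attach conspecific sequence tips as a star under each species tip
    for leaf in list(tree.leaf_node_iter()):
        species, genus = leaf.species_name, leaf.genus_name
        if leaf.taxon is not None:
            leaf.taxon = None
        for j in range(1, config.seqs_per_species + 1):
            child = leaf.new_child(edge_length=t_within / 2.0)
            child.taxon = tree.taxon_namespace.new_taxon(f"{species}_{j:02d}")
            child.species_name = species
            child.genus_name = genus
    for node in tree.preorder_node_iter():
        if not node.is_leaf():
            node.taxon = None
    tree.taxon_namespace = dendropy.TaxonNamespace(
        [lf.taxon for lf in tree.leaf_node_iter()])
    return PhyloTree(tree)


def _graft(tip: dendropy.Node, sub: dendropy.Tree) -> None:
    for child in sub.seed_node.child_nodes():
        tip.add_child(child)


# ---------------------------------------------------------------------------
# Sequence evolution

def evolve_sequences(tree: PhyloTree, config: SimulationConfig
                     ) -> tuple[Alignment, SyntheticTruth]:
    """Evolve an alignment down the tree under JC69 and record the truth.

    The root sequence is uniform over {A,C,G,T}; each branch substitutes
    sites independently with probability (3/4)(1 - exp(-4t/3)), the new
    base uniform among the three alternatives. Gap runs and ambiguity
    codes are then injected at the configured rates, and the realized
    maximum within-species divergence is recomputed on the final
    alignment with a direct pairwise scan.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 1]).generate_state(1)[0])
    n_cols = config.n_columns
    root = tree.tree.seed_node
    root.seq_idx = rng.integers(0, 4, size=n_cols).astype(np.uint8)
    for node in tree.tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        t = node.edge.length or 0.0
        p = 0.75 * (1.0 - np.exp(-4.0 * t / 3.0))
        seq = node.parent_node.seq_idx.copy()
        if p > 0:
            hit = np.flatnonzero(rng.random(n_cols) < p)
            if hit.size:
                seq[hit] = (seq[hit] + rng.integers(1, 4, size=hit.size)) % 4
        node.seq_idx = seq

    members = []
    species_of: dict[str, str] = {}
    genus_of: dict[str, str] = {}
    for leaf in tree.tree.leaf_node_iter():
        acc = leaf.taxon.label
        chars = np.array(list("ACGT"), dtype="U1")[leaf.seq_idx]
        # indel runs: geometric lengths, replacing residues with gaps
        starts = np.flatnonzero(rng.random(n_cols) < config.indel_rate)
        for s in starts:
            length = 1 + rng.geometric(1.0 / config.indel_mean_length)
            chars[s:s + length] = "-"
        # ambiguity codes containing the true base
        amb = np.flatnonzero((rng.random(n_cols) < config.ambiguity_rate)
                             & (chars != "-"))
        for s in amb:
            base_idx = int(leaf.seq_idx[s])
            pool = _AMBIG_FOR[base_idx] + "N"
            chars[s] = pool[rng.integers(len(pool))]
        species_of[acc] = leaf.species_name
        genus_of[acc] = leaf.genus_name
        members.append(AlignedSequence(
            acc, "".join(chars),
            {"species": leaf.species_name, "genus": leaf.genus_name}))

    aln = Alignment(members)
    truth = SyntheticTruth(
        species_of=species_of,
        genus_of=genus_of,
        max_within_divergence=_realized_within(aln, species_of),
        newick=tree.write(),
    )
    return aln, truth


def _realized_within(aln: Alignment, species_of: dict[str, str],
                     max_indel: int = 20) -> dict[str, float]:
    """Max pairwise divergence per species, by direct column scanning.

    Intentionally a plain re-derivation (gap-vs-base counts, gap-vs-gap
    excluded, gap runs longer than *max_indel* excluded, ambiguity codes
    match when their sets intersect) so the truth record is filled
    independently of the distance code the pipeline uses.
    """
    by_species: dict[str, list[str]] = {}
    for acc, sp in species_of.items():
        by_species.setdefault(sp, []).append(acc)
    out = {}
    for sp, accs in by_species.items():
        best = 0.0
        for i, a in enumerate(accs):
            for b in accs[i + 1:]:
                best = max(best, _scan_distance(
                    aln.get(a).residues, aln.get(b).residues, max_indel))
        out[sp] = best
    return out


def _scan_distance(sa: str, sb: str, max_indel: int) -> float:
    def long_runs(s: str) -> set[int]:
        cols, run = set(), []
        for i, ch in enumerate(s + "X"):
            if ch == "-":
                run.append(i)
            else:
                if len(run) > max_indel:
                    cols.update(run)
                run = []
        return cols

    skip = long_runs(sa) | long_runs(sb)
    diffs = comparable = 0
    for i, (x, y) in enumerate(zip(sa, sb)):
        if i in skip or (x == "-" and y == "-"):
            continue
        comparable += 1
        if x == "-" or y == "-":
            diffs += 1
        elif not (iupac.MASK[x] & iupac.MASK[y]):
            diffs += 1
    return diffs / comparable if comparable else 0.0


# ---------------------------------------------------------------------------
# Barcode planting

def plant_barcode(aln: Alignment, truth: SyntheticTruth,
                  species: str, spec: PlantedBarcodeSpec,
                  region_map: RegionMap, seed: int) -> tuple[Alignment, SyntheticTruth]:
    """Plant a diagnostic motif for one species and guarantee separation.

    All members of the target species receive an identical random motif
    in a gap-free window of the requested region; every other sequence is
    minimally edited until it differs from the motif at >=
    ``min_separation`` window positions. No-op edits: sequences already
    sufficiently distant are left untouched.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]).generate_state(1)[0])
    r0, r1 = region_map.span(spec.region)
    if r1 - r0 + 1 < spec.length:
        raise ValueError(f"region {spec.region} shorter than the motif")
    if spec.min_separation > spec.length:
        raise ValueError("separation cannot exceed the window length")
    targets = [a for a, sp in truth.species_of.items() if sp == species]
    if not targets:
        raise ValueError(f"unknown species {species!r}")

    grid = np.array([list(aln.get(a).residues) for a in aln.accessions])
    rows = {a: i for i, a in enumerate(aln.accessions)}
    t_rows = [rows[a] for a in targets]

    # candidate starts where every target member is gap-free
    ok_starts = []
    for s in range(r0 - 1, r1 - spec.length + 1):
        if (grid[t_rows, s:s + spec.length] != "-").all():
            ok_starts.append(s)
    if not ok_starts:
        raise ValueError("no gap-free window available for the target")
    start = int(ok_starts[rng.integers(len(ok_starts))])
    motif = np.array(list("ACGT"), dtype="U1")[
        rng.integers(0, 4, size=spec.length)]

    already = (grid[t_rows, start:start + spec.length] == motif).all()
    if not already:
        grid[t_rows, start:start + spec.length] = motif

    d_out_min = None
    for i, acc in enumerate(aln.accessions):
        if acc in set(targets):
            continue
        window = grid[i, start:start + spec.length]
        diff = _window_diffs(window, motif)
        need = spec.min_separation - int(diff.sum())
        if need > 0:
            editable = np.flatnonzero(~diff)
            picks = rng.choice(editable, size=need, replace=False)
            for pos in picks:
                base = motif[pos]
                others = [b for b in "ACGT" if b != base]
                grid[i, start + pos] = others[rng.integers(3)]
            diff = _window_diffs(grid[i, start:start + spec.length], motif)
        d = int(diff.sum())
        d_out_min = d if d_out_min is None else min(d_out_min, d)

    members = [AlignedSequence(m.accession, "".join(grid[rows[m.accession]]),
                               dict(m.taxon_labels)) for m in aln.members]
    new_aln = Alignment(members)
    truth.planted = PlantedTruth(
        region=spec.region,
        window_columns=(start + 1, start + spec.length),
        positions=_region_positions(new_aln, targets[0], region_map,
                                    spec.region, start + 1, start + spec.length),
        barcode="".join(motif).lower(),
        target_species=species,
        expected_d_out=int(d_out_min) if d_out_min is not None else 0,
    )
    truth.max_within_divergence = _realized_within(new_aln, truth.species_of)
    return new_aln, truth


def _window_diffs(window: np.ndarray, motif: np.ndarray) -> np.ndarray:
    out = np.zeros(len(motif), dtype=bool)
    for k, (x, y) in enumerate(zip(window, motif)):
        if x == "-":
            out[k] = True
        elif not (iupac.MASK[x] & iupac.MASK[y]):
            out[k] = True
    return out


def _region_positions(aln: Alignment, accession: str, region_map: RegionMap,
                      region: str, c0: int, c1: int) -> tuple[int, int]:
    from .alignment import CoordinateIndex
    index = CoordinateIndex(aln, region_map)
    _, p0 = index.column_to_region_position(accession, c0)
    _, p1 = index.column_to_region_position(accession, c1)
    return p0, p1


# ---------------------------------------------------------------------------
# Datasets

@dataclass
class SyntheticDataset:
    alignment: Alignment
    region_map: RegionMap
    tree: PhyloTree
    truth: SyntheticTruth
    config: SimulationConfig

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "alignment.fasta",
            "taxa": outdir / "taxa.tsv",
            "regions": outdir / "regions.json",
            "tree": outdir / "tree.nwk",
            "truth": outdir / "truth.json",
        }
        write_alignment(paths["fasta"], self.alignment)
        write_taxon_map(paths["taxa"], {
            m.accession: m.taxon_labels for m in self.alignment.members})
        self.region_map.to_json(paths["regions"])
        paths["tree"].write_text(self.truth.newick + "\n")
        paths["truth"].write_text(self.truth.to_json() + "\n")
        return paths


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """One fully-specified synthetic study: tree, alignment, truth."""
    tree = simulate_tree(config)
    aln, truth = evolve_sequences(tree, config)
    region_map = config.region_map()
    if config.planted is not None:
        target = config.planted.target_species or "sp01"
        aln, truth = plant_barcode(aln, truth, target, config.planted,
                                   region_map, config.seed)
    return SyntheticDataset(aln, region_map, tree, truth, config)


def load_dataset(directory: str | Path) -> SyntheticDataset:
    """Re-read an emitted dataset and cross-validate its parts."""
    directory = Path(directory)
    aln = read_alignment(directory / "alignment.fasta", directory / "taxa.tsv")
    region_map = RegionMap.from_json(directory / "regions.json", aln.n_columns)
    truth = SyntheticTruth.from_json((directory / "truth.json").read_text())
    tree = PhyloTree.read(directory / "tree.nwk")
    if set(truth.species_of) != set(aln.accessions):
        raise ValueError("truth record and alignment disagree on accessions")
    if set(tree.leaves) != set(aln.accessions):
        raise ValueError("tree and alignment disagree on accessions")
    for m in aln.members:
        if m.taxon_labels.get("species") != truth.species_of[m.accession]:
            raise ValueError(f"species label mismatch for {m.accession}")
    cfg = SimulationConfig(seed=0, region_lengths={
        name: region_map.length(name)
        for name in region_map.entries if name != "full"})
    return SyntheticDataset(aln, region_map, tree, truth, cfg)


def planted_genus_config(seed: int) -> SimulationConfig:
    """Study conditions for planted-genus delimitation experiments.

    Genus boundaries are recoverable under the breadth criterion only
    when the upper breadth band around the reference genus cannot reach
    across genera, i.e. band_hi x (within-genus breadth) < between-genus
    patristic distance. With the default 2.0x band this dictates clearly
    separated tiers: 0.5% within species, 5% between congeneric species
    and 30% between genera.
    """
    return SimulationConfig(
        n_species=9, n_genera=3, seqs_per_species=3,
        within_divergence=0.005, between_divergence=0.05,
        between_genus_divergence=0.30, seed=seed,
    )


def planted_recovery_config(seed: int) -> SimulationConfig:
    """Study conditions for planted-barcode recovery experiments.

    Ten species of five sequences each with tight conspecific clusters
    (0.5%) and low interspecific divergence (2%), so that windows away
    from the planted motif rarely accumulate more than one
    lineage-private difference; a 25-base motif with guaranteed
    separation >= 3 is planted in ITS2.
    """
    return SimulationConfig(
        n_species=10, seqs_per_species=5,
        within_divergence=0.005, between_divergence=0.02,
        planted=PlantedBarcodeSpec(length=25, min_separation=3,
                                   region="ITS2"),
        seed=seed,
    )
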