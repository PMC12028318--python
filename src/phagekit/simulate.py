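"""Synthetic study-condition generators with attached ground truth.

Three generators emulate the statistical structure of a broad-host-range
vibriophage study so every analysis stage runs with no external data:

* a modular cross-infection matrix (generalist and specialist phages,
  resistant / slightly susceptible / susceptible hosts, log-normal titers
  clipped to the observed 1e2..1e8 PFU/ml range);
* phage proteomes evolved on a known rooted tree with a conserved core
  backbone, accessory islands gained and lost on scripted branches, and
  homologous-recombination injections at hotspot genes recorded with true
  coordinates;
* noisy one-step growth and adsorption curves with known burst size,
  latent period and adsorption rate.

Determinism: a single integer seed drives one named pseudo-random stream
per generator (``default_rng([seed, stream])``), so the three generators
are independent and each is byte-reproducible under a fixed seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .genomes import GeneCall, Proteome, write_protein_fasta, write_proteome_gff
from .interactions import EntryState, HostClass, TiterEntry, TiterMatrix
from .lifehistory import KineticSeries
from .recombination import (
    BranchType,
    FamilyAlignment,
    GeneCoordinateMap,
    RecombinationEvent,
    concat_gene_coordinates,
    write_family_alignment,
    write_recombination_gff,
)

__all__ = [
    "MatrixTruth",
    "simulate_infection_matrix",
    "GenomeTruth",
    "SimulatedGenomes",
    "simulate_phage_genomes",
    "KineticsTruth",
    "SimulatedKinetics",
    "simulate_kinetics",
]

# stream tags: one independent RNG stream per generator under a shared seed
_STREAM_MATRIX = 1
_STREAM_GENOMES = 2
_STREAM_KINETICS = 3

LOG10_TITER_MIN = 2.0  # detection-limit side of the observed titer range
LOG10_TITER_MAX = 8.0


# ---------------------------------------------------------------------------
# Infection matrix
# ---------------------------------------------------------------------------

@dataclass
class MatrixTruth:
    """Scripted structure behind a simulated cross-infection matrix."""

    phage_archetype: dict[str, str]  # phage -> "generalist" | "specialist"
    host_class: dict[str, HostClass]
    pair_log10_mean: dict[tuple[str, str], float]  # compatible pairs only
    noise_sd: float
    seed: int


def simulate_infection_matrix(
    n_phages: int = 18,
    n_hosts: int = 157,
    frac_specialists: float = 3 / 18,
    class_mix: tuple[float, float, float] = (0.40, 0.30, 0.30),
    noise_sd: float = 0.3,
    seed: int = 0,
    *,
    specialist_host_fraction: float = 0.10,
    impaired_fraction: float = 0.15,
    generalist_log10_titer: float = 6.0,
    specialist_log10_titer: float = 8.0,
    weak_log10_titer: float = 3.5,
) -> tuple[TiterMatrix, MatrixTruth]:
    """Simulate a modular phage x host titer matrix with known structure.

    ``class_mix`` gives the expected (resistant, slightly susceptible,
    susceptible) host proportions.  Generalist phages infect every
    susceptible host around ``generalist_log10_titer``; each slightly
    susceptible host is reached by two generalists at a weak titer;
    specialists infect a high-titer subset of susceptible hosts sized at
    ``specialist_host_fraction`` of the whole panel.  Titers are drawn log-normally (sd ``noise_sd`` log10 units)
    and clipped to the observed 1e2..1e8 PFU/ml range.  Resistant hosts
    receive no positive entry; a fraction of their cells are the
    resistant-but-impaired state (adsorption without productive
    infection).
    """
    if n_phages < 2 or n_hosts < 2:
        raise ValueError("need at least 2 phages and 2 hosts")
    if not (0 <= frac_specialists <= 1):
        raise ValueError("frac_specialists must be in [0, 1]")
    if abs(sum(class_mix) - 1.0) > 1e-9:
        raise ValueError("class_mix must sum to 1")
    rng = np.random.default_rng([seed, _STREAM_MATRIX])

    n_specialists = round(frac_specialists * n_phages)
    if frac_specialists > 0 and n_specialists == 0:
        raise ValueError(
            f"frac_specialists={frac_specialists} yields an expected specialist count of 0"
        )
    n_generalists = n_phages - n_specialists

    class_counts = [round(f * n_hosts) for f in class_mix]
    class_counts[2] = n_hosts - class_counts[0] - class_counts[1]
    for frac, count in zip(class_mix, class_counts):
        if frac > 0 and count <= 0:
            raise ValueError(f"class_mix fraction {frac} yields an expected size of 0")

    phage_ids = [f"phage{i:02d}" for i in range(n_phages)]
    host_ids = [f"host{j:03d}" for j in range(n_hosts)]
    archetype = {
        pid: ("specialist" if i < n_specialists else "generalist")
        for i, pid in enumerate(phage_ids)
    }
    shuffled = list(rng.permutation(host_ids))
    host_class: dict[str, HostClass] = {}
    classes = (
        [HostClass.RESISTANT] * class_counts[0]
        + [HostClass.SLIGHTLY_SUSCEPTIBLE] * class_counts[1]
        + [HostClass.SUSCEPTIBLE] * class_counts[2]
    )
    for hid, cls in zip(shuffled, classes):
        host_class[hid] = cls

    susceptible = [h for h in host_ids if host_class[h] is HostClass.SUSCEPTIBLE]
    slight = [h for h in host_ids if host_class[h] is HostClass.SLIGHTLY_SUSCEPTIBLE]
    generalists = [p for p in phage_ids if archetype[p] == "generalist"]
    specialists = [p for p in phage_ids if archetype[p] == "specialist"]

    pair_mean: dict[tuple[str, str], float] = {}
    for phage in generalists:
        for host in susceptible:
            pair_mean[(phage, host)] = generalist_log10_titer
    for host in slight:
        n_pick = min(2, len(generalists))
        for phage in rng.choice(generalists, size=n_pick, replace=False):
            pair_mean[(str(phage), host)] = weak_log10_titer
    n_target = max(1, round(specialist_host_fraction * n_hosts))
    for phage in specialists:
        n_pick = min(n_target, len(susceptible))
        if n_pick == 0:
            raise ValueError("no susceptible hosts available for specialist phages")
        for host in rng.choice(susceptible, size=n_pick, replace=False):
            pair_mean[(phage, str(host))] = specialist_log10_titer

    entries: list[list[TiterEntry]] = []
    for phage in phage_ids:
        row = []
        for host in host_ids:
            mean = pair_mean.get((phage, host))
            if mean is None:
                if (
                    host_class[host] is HostClass.RESISTANT
                    and rng.random() < impaired_fraction
                ):
                    row.append(TiterEntry(state=EntryState.IMPAIRED))
                else:
                    row.append(TiterEntry(state=EntryState.RESISTANT))
            else:
                log10_titer = float(
                    np.clip(
                        mean + rng.normal(0.0, noise_sd) if noise_sd > 0 else mean,
                        LOG10_TITER_MIN,
                        LOG10_TITER_MAX,
                    )
                )
                row.append(TiterEntry(state=EntryState.TITER, value=10.0 ** log10_titer))
        entries.append(row)

    matrix = TiterMatrix(
        phage_ids=phage_ids,
        host_ids=host_ids,
        entries=entries,
        provenance=f"simulate_infection_matrix(seed={seed})",
    )
    truth = MatrixTruth(archetype, host_class, pair_mean, noise_sd, seed)
    return matrix, truth


# ---------------------------------------------------------------------------
# Phage genomes
# ---------------------------------------------------------------------------

_CODON_TABLE = CodonTable.unambiguous_dna_by_id[1]
_BASES = "ATCG"
_SENSE_CODONS = sorted(_CODON_TABLE.forward_table)


@dataclass
class GenomeTruth:
    """Scripted evolutionary history behind a simulated genome set."""

    tree_newick: str
    family_of_gene: dict[tuple[str, str], str]
    core_families: list[str]
    accessory_families: list[str]
    island_position: dict[str, int]  # accessory family -> gene-order position
    gains: dict[str, frozenset[str]]  # accessory family -> clade of the gain branch
    losses: dict[str, frozenset[frozenset[str]]]
    injected_families: list[str]
    seed: int


@dataclass
class SimulatedGenomes:
    """Genome set plus every derived artifact the analysis stages read."""

    proteomes: list[Proteome]
    alignments: dict[str, FamilyAlignment]  # per family, codons included
    coordinates: GeneCoordinateMap  # core families, reference gene order
    events: list[RecombinationEvent]
    presence: pd.DataFrame  # family x genome 0/1
    truth: GenomeTruth

    def write(self, out_dir: str | Path) -> None:
        """Emit all artifacts as the plain-text formats the readers accept."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for proteome in self.proteomes:
            write_protein_fasta(proteome, out / f"{proteome.genome_id}.faa")
            write_proteome_gff(proteome, out / f"{proteome.genome_id}.gff")
        aln_dir = out / "alignments"
        aln_dir.mkdir(exist_ok=True)
        for family_id, aln in self.alignments.items():
            write_family_alignment(aln, aln_dir / f"{family_id}.codon.fasta")
        write_recombination_gff(self.events, out / "recombination.gff")
        (out / "tree.nwk").write_text(self.truth.tree_newick + "\n")
        self.presence.to_csv(out / "presence_absence.tsv", sep="\t")


def _random_rooted_tree(n_taxa: int, height: float, rng: np.random.Generator) -> dendropy.Tree:
    """Random bifurcating rooted tree scaled to root-to-tip height."""
    taxa = [f"taxon{i:02d}" for i in range(n_taxa)]
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_taxa,
        rng=random.Random(int(rng.integers(2**31))),
    )
    for leaf, label in zip(tree.leaf_node_iter(), taxa):
        leaf.taxon.label = label
    depths = tree.calc_node_root_distances(return_leaf_distances_only=True)
    scale = height / max(depths)
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= scale
    return tree


def _evolve_codons(
    parent: np.ndarray, branch_length: float, rng: np.random.Generator
) -> np.ndarray:
    """Per-site substitution along one branch; stop-creating changes revert."""
    child = parent.copy()
    n = len(child)
    mutate = rng.random(n) < branch_length
    for pos in np.nonzero(mutate)[0]:
        old = child[pos]
        choices = [b for b in _BASES if b != old]
        child[pos] = choices[int(rng.integers(3))]
        codon_start = 3 * (pos // 3)
        codon = "".join(child[codon_start : codon_start + 3])
        if codon in _CODON_TABLE.stop_codons:
            child[pos] = old
    return child


def _script_gain_and_losses(
    tree: dendropy.Tree,
    clade: Mapping[dendropy.Node, frozenset[str]],
    rng: np.random.Generator,
    max_losses: int = 2,
) -> tuple[frozenset[str], list[frozenset[str]], frozenset[str]]:
    """Pick a gain branch and canonical loss branches; returns present leaves.

    Losses are chosen so that the scripted placement is exactly the Dollo
    reconstruction of the induced presence pattern: loss subtrees are
    disjoint, each loss node's siblings keep at least one present leaf,
    and both children of the gain node keep presence (so the most recent
    common ancestor of the present leaves stays the gain node).
    """
    nodes = list(tree.preorder_node_iter())
    gain = nodes[int(rng.integers(len(nodes)))]
    present = set(clade[gain])
    losses: list[frozenset[str]] = []
    if not gain.is_leaf():
        candidates = [n for n in gain.preorder_iter() if n is not gain]
        rng.shuffle(candidates)
        for cand in candidates:
            if len(losses) >= max_losses:
                break
            sub = clade[cand]
            if not sub <= present:
                continue
            remaining = present - sub
            if not remaining:
                continue
            parent = cand.parent_node
            siblings = frozenset().union(
                *(clade[c] for c in parent.child_nodes() if c is not cand)
            )
            if not siblings & remaining:
                continue  # loss would float up to the parent branch
            if any(
                not (clade[child] & remaining) for child in gain.child_nodes()
            ):
                continue  # would move the gain below its scripted branch
            present = remaining
            losses.append(sub)
    return clade[gain], losses, frozenset(present)


def simulate_phage_genomes(
    n_taxa: int = 18,
    n_core: int = 250,
    n_accessory: int = 40,
    hotspot_positions: Sequence[int] | None = None,
    subst_rate: float = 0.02,
    recomb_events: int = 9,
    seed: int = 0,
    *,
    gene_length_codons: tuple[int, int] = (60, 140),
    hotspot_width: int = 4,
    donor_divergence: float = 0.15,
) -> SimulatedGenomes:
    """Evolve a phage genome collection with known families and events.

    Core families are evolved by per-site nucleotide substitution along a
    random rooted tree of height ``subst_rate`` substitutions/site (stop
    codons rejected).  Accessory families live on two island positions by
    default (or ``hotspot_positions``), gained and lost on scripted
    branches.  ``recomb_events`` whole-gene recombination injections copy
    into a recipient clade the allele of an unsampled donor lineage
    (the family ancestor evolved along a ghost branch of length
    ``donor_divergence`` substitutions/site), so recombined families carry
    excess divergence; every event is recorded with true coordinates on
    the concatenated core alignment.
    """
    if n_core < 2:
        raise ValueError("need at least 2 core families")
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    rng = np.random.default_rng([seed, _STREAM_GENOMES])
    if hotspot_positions is None:
        hotspot_positions = [n_core // 2, (4 * n_core) // 5]
    for pos in hotspot_positions:
        if not (0 <= pos < n_core):
            raise ValueError(f"hotspot position {pos} outside gene-order range [0, {n_core})")

    tree = _random_rooted_tree(n_taxa, height=subst_rate, rng=rng)
    taxa = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    clade: dict[dendropy.Node, frozenset[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            clade[node] = frozenset([node.taxon.label])
        else:
            clade[node] = frozenset().union(*(clade[c] for c in node.child_nodes()))

    core_ids = [f"core{i:04d}" for i in range(n_core)]
    acc_ids = [f"acc{i:04d}" for i in range(n_accessory)]

    # evolve every family along the tree at codon level
    family_tip_codons: dict[str, dict[str, str]] = {}
    family_ancestral: dict[str, np.ndarray] = {}
    lengths: dict[str, int] = {}
    for family_id in core_ids + acc_ids:
        n_codons = int(rng.integers(gene_length_codons[0], gene_length_codons[1] + 1))
        lengths[family_id] = n_codons
        ancestral = np.array(
            list("".join(_SENSE_CODONS[i] for i in rng.integers(len(_SENSE_CODONS), size=n_codons)))
        )
        family_ancestral[family_id] = ancestral
        tips: dict[str, str] = {}
        node_seq = {tree.seed_node: ancestral}
        for node in tree.preorder_node_iter():
            if node is tree.seed_node:
                continue
            node_seq[node] = _evolve_codons(
                node_seq[node.parent_node], node.edge.length, rng
            )
            if node.is_leaf():
                tips[node.taxon.label] = "".join(node_seq[node])
        family_tip_codons[family_id] = tips

    # scripted accessory gain/loss; presence of core is everywhere
    island_position: dict[str, int] = {}
    gains: dict[str, frozenset[str]] = {}
    losses: dict[str, frozenset[frozenset[str]]] = {}
    present_leaves: dict[str, frozenset[str]] = {fid: frozenset(taxa) for fid in core_ids}
    for idx, family_id in enumerate(acc_ids):
        island_position[family_id] = int(hotspot_positions[idx % len(hotspot_positions)])
        gain, loss_list, present = _script_gain_and_losses(tree, clade, rng)
        gains[family_id] = gain
        losses[family_id] = frozenset(loss_list)
        present_leaves[family_id] = present

    # recombination injections at hotspot core families (whole-gene replacement)
    hotspot_families: list[str] = []
    for pos in hotspot_positions:
        lo, hi = max(0, pos - hotspot_width), min(n_core, pos + hotspot_width + 1)
        hotspot_families.extend(core_ids[lo:hi])
    coordinates = concat_gene_coordinates([(fid, 3 * lengths[fid]) for fid in core_ids])
    events: list[RecombinationEvent] = []
    injected: list[str] = []
    internal_nodes = [
        n for n in tree.preorder_node_iter()
        if n is not tree.seed_node and len(clade[n]) < n_taxa - 1
    ]
    for _ in range(recomb_events):
        family_id = hotspot_families[int(rng.integers(len(hotspot_families)))]
        recipient = internal_nodes[int(rng.integers(len(internal_nodes)))]
        recipients = clade[recipient]
        # the donor is a diverged allele from outside the sampled collection:
        # evolve the family ancestor along an extra-long ghost branch
        donor_seq = "".join(
            _evolve_codons(family_ancestral[family_id], donor_divergence, rng)
        )
        for taxon in recipients:
            family_tip_codons[family_id][taxon] = donor_seq
        start, end = coordinates.interval(family_id)
        events.append(
            RecombinationEvent(
                start=start,
                end=end,
                branch_type=(
                    BranchType.INTERNAL if len(recipients) > 1 else BranchType.TERMINAL
                ),
                affected_taxa=recipients,
            )
        )
        injected.append(family_id)

    # assemble per-genome ordered gene calls
    spacer = 50
    proteomes: list[Proteome] = []
    family_of_gene: dict[tuple[str, str], str] = {}
    for taxon in taxa:
        order: list[str] = []
        for pos, core_id in enumerate(core_ids):
            islands_here = sorted(
                fid
                for fid in acc_ids
                if island_position[fid] == pos and taxon in present_leaves[fid]
            )
            order.extend(islands_here)
            order.append(core_id)
        genes = []
        cursor = 0
        for rank, family_id in enumerate(order):
            nt = family_tip_codons[family_id][taxon]
            gene_id = f"{taxon}_g{rank:04d}"
            genes.append(
                GeneCall(
                    genome_id=taxon,
                    gene_id=gene_id,
                    rank=rank,
                    strand="+",
                    start=cursor,
                    end=cursor + len(nt),
                    protein=str(Seq(nt).translate()),
                )
            )
            family_of_gene[(taxon, gene_id)] = family_id
            cursor += len(nt) + spacer
        proteomes.append(Proteome(genome_id=taxon, genes=genes))

    # per-family alignments (no indels simulated, so sequences align as-is)
    alignments: dict[str, FamilyAlignment] = {}
    for family_id in core_ids + acc_ids:
        members = {
            taxon: family_tip_codons[family_id][taxon]
            for taxon in sorted(present_leaves[family_id])
        }
        if not members:
            continue
        proteins = {t: str(Seq(s).translate()) for t, s in members.items()}
        alignments[family_id] = FamilyAlignment(family_id, proteins, members)

    presence = pd.DataFrame(
        {
            taxon: [int(taxon in present_leaves[fid]) for fid in core_ids + acc_ids]
            for taxon in taxa
        },
        index=core_ids + acc_ids,
    )
    presence = presence[presence.sum(axis=1) > 0]

    tree_newick = tree.as_string(schema="newick", suppress_rooting=True).strip()
    truth = GenomeTruth(
        tree_newick=tree_newick,
        family_of_gene=family_of_gene,
        core_families=core_ids,
        accessory_families=[fid for fid in acc_ids if fid in presence.index],
        island_position=island_position,
        gains=gains,
        losses=losses,
        injected_families=sorted(set(injected)),
        seed=seed,
    )
    return SimulatedGenomes(proteomes, alignments, coordinates, events, presence, truth)


# ---------------------------------------------------------------------------
# Kinetics
# ---------------------------------------------------------------------------

@dataclass
class KineticsTruth:
    burst_size: float
    latent_period: float
    adsorption_rate: float
    adsorption_duration: float
    baseline: float
    input_titer: float
    seed: int


@dataclass
class SimulatedKinetics:
    growth: list[KineticSeries]
    adsorption: list[KineticSeries]
    truth: KineticsTruth

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, series_list in (("growth", self.growth), ("adsorption", self.adsorption)):
            rows = []
            for series in series_list:
                for t, v in zip(series.times, series.values):
                    rows.append({"time": t, "value": v, "replicate": series.replicate_id})
            pd.DataFrame(rows).to_csv(out / f"{name}.csv", index=False)


def simulate_kinetics(
    burst: float = 38.0,
    latent: float = 35.0,
    adsorption_rate: float = 0.5,
    noise_sd: float = 0.0,
    time_grid: Sequence[float] | None = None,
    n_replicates: int = 4,
    seed: int = 0,
    *,
    adsorption_duration: float = 5.0,
    baseline: float = 10.0,
    input_titer: float = 1e7,
    rise_duration: float = 20.0,
) -> SimulatedKinetics:
    """Simulate one-step growth and adsorption curves with known traits.

    Growth curves hold an infection-center baseline until the end of the
    latent period (``latent - adsorption_duration`` on the culture clock),
    rise smoothly over ``rise_duration`` minutes to a plateau at
    ``baseline * burst``, and carry multiplicative log-normal noise of
    relative magnitude ``noise_sd``.  Adsorption curves decay
    exponentially from ``input_titer`` at ``adsorption_rate`` per minute.
    """
    if burst <= 1:
        raise ValueError("burst must exceed 1 (otherwise no rise exists)")
    grid = np.asarray(
        time_grid if time_grid is not None else np.arange(0.0, 121.0, 10.0), dtype=float
    )
    rise_start = latent - adsorption_duration
    if rise_start >= grid[-1]:
        raise ValueError(f"latent period {latent} lies beyond the time grid")
    if rise_start < grid[1]:
        raise ValueError("latent period leaves fewer than 2 pre-rise points")
    rng = np.random.default_rng([seed, _STREAM_KINETICS])

    x = np.clip((grid - rise_start) / rise_duration, 0.0, 1.0)
    smooth = x * x * (3.0 - 2.0 * x)
    clean = baseline * (1.0 + (burst - 1.0) * smooth)

    growth = []
    for rep in range(n_replicates):
        noise = np.exp(rng.normal(0.0, noise_sd, size=len(grid))) if noise_sd > 0 else 1.0
        growth.append(KineticSeries(grid.copy(), clean * noise, f"rep{rep + 1}"))

    ads_clean = input_titer * np.exp(-adsorption_rate * grid)
    adsorption = []
    for rep in range(n_replicates):
        noise = np.exp(rng.normal(0.0, noise_sd, size=len(grid))) if noise_sd > 0 else 1.0
        adsorption.append(KineticSeries(grid.copy(), ads_clean * noise, f"rep{rep + 1}"))

    truth = KineticsTruth(
        burst_size=burst,
        latent_period=latent,
        adsorption_rate=adsorption_rate,
        adsorption_duration=adsorption_duration,
        baseline=baseline,
        input_titer=input_titer,
        seed=seed,
    )
    return SimulatedKinetics(growth, adsorption, truth)
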