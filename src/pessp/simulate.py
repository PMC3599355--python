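"""Synthetic protein families and assay data for end-to-end testing.

The generator emulates the situation the prediction pipeline is built for:
a protein family evolved along a known tree in which one clade (the planted
subgroup) shares a substrate specificity, a handful of its members carrying
experimentally defined labels and the rest being uncharacterized. Sequences
evolve under a Poisson-style model: along a branch of length b each site
substitutes with probability 1 - exp(-b), to a uniformly chosen different
residue, with no indels (gapless truth alignments keep distance checks
exact). Kinetic data are Michaelis-Menten rates with multiplicative
Gaussian noise. All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align import pairwise_global_align, percent_identity
from .records import AMINO_ACIDS, ProteinRecord
from .kinetics import KineticPoint, michaelis_menten_rate
from .tree import Node, Tree

DEFAULT_TARGET_FUNCTION = "mandelonitrile hydrolase"
#: substrate grid spanning the 0.1-15 mM assay range
DEFAULT_S_GRID = (0.1, 0.2, 0.5, 1.0, 2.0, 5.0, 10.0, 15.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Study geometry: 39 taxa, a 12-member subgroup, 5 labeled positives.

    ``separation_factor`` is the ratio of the subgroup's stem length to the
    mean within-subgroup root-to-leaf depth; >= 3 gives clean separation
    between within- and between-group divergence.
    """

    n_taxa: int = 39
    subgroup_size: int = 12
    n_labeled_positives: int = 5
    root_length: int = 300  # residues
    mean_branch_length: float = 0.05  # substitutions/site
    separation_factor: float = 3.0
    seed: int = 0
    target_function: str = DEFAULT_TARGET_FUNCTION

    def __post_init__(self) -> None:
        if not (1 <= self.n_labeled_positives <= self.subgroup_size <= self.n_taxa):
            raise ValueError("require n_labeled_positives <= subgroup_size <= n_taxa")
        if self.subgroup_size >= self.n_taxa:
            raise ValueError("subgroup_size must be smaller than n_taxa")
        if self.separation_factor < 1:
            raise ValueError("separation_factor must be >= 1")
        if self.root_length < 1 or self.mean_branch_length < 0:
            raise ValueError("invalid root_length or mean_branch_length")


def _accession(i: int) -> str:
    return f"SYN_{i + 1:06d}"


def _branch_length(rng: np.random.Generator, mean_bl: float) -> float:
    # Uniform in [0.5, 1.5] x mean: mean equals mean_branch_length while the
    # support stays bounded away from zero, so every simulated edge carries a
    # resolvable expected number of substitutions at the default sequence
    # length (an edge shorter than ~1/root_length is invisible to any
    # tree-estimation method and would not occur in a curated family).
    return float(rng.uniform(0.5 * mean_bl, 1.5 * mean_bl))


def _join_random(nodes: list[Node], rng: np.random.Generator, mean_bl: float) -> Node:
    nodes = list(nodes)
    while len(nodes) > 1:
        i, j = sorted(int(x) for x in rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        a.length = _branch_length(rng, mean_bl) if a.length is None else a.length
        b.length = _branch_length(rng, mean_bl) if b.length is None else b.length
        nodes.append(Node(children=[a, b]))
    return nodes[0]


def _mean_depth(node: Node) -> float:
    depths = []

    def walk(n: Node, d: float) -> None:
        if n.is_leaf:
            depths.append(d)
        for c in n.children:
            walk(c, d + (c.length or 0.0))

    walk(node, 0.0)
    return float(np.mean(depths)) if depths else 0.0


def simulate_tree(cfg: SimulationConfig) -> tuple[Tree, frozenset[str]]:
    """Random binary tree with one marked subgroup clade.

    The subgroup ancestor's stem length equals
    ``separation_factor x mean within-subgroup depth``, planting a clade
    whose members are closer to each other than to anything outside.
    """
    rng = np.random.default_rng([cfg.seed, 11])
    names = [_accession(i) for i in range(cfg.n_taxa)]
    subgroup = frozenset(names[: cfg.subgroup_size])
    sub_root = _join_random([Node(name=x) for x in names[: cfg.subgroup_size]], rng,
                            cfg.mean_branch_length)
    out_nodes = [Node(name=x) for x in names[cfg.subgroup_size:]]
    out_root = _join_random(out_nodes, rng, cfg.mean_branch_length)

    within_depth = _mean_depth(sub_root) or cfg.mean_branch_length
    sub_root.length = cfg.separation_factor * within_depth
    if out_root.length is None:
        out_root.length = _branch_length(rng, cfg.mean_branch_length)
    return Tree(Node(children=[sub_root, out_root])), subgroup


def random_binary_tree(
    n_leaves: int, rng: np.random.Generator, mean_branch_length: float = 0.1
) -> Tree:
    """Random binary tree with exponential branch lengths (leaves T01, T02, ...)."""
    if n_leaves < 3:
        raise ValueError("need at least 3 leaves")
    leaves = [Node(name=f"T{i + 1:02d}") for i in range(n_leaves)]
    return Tree(_join_random(leaves, rng, mean_branch_length))


def subgroup_root(tree: Tree, subgroup: frozenset[str]) -> Node:
    """The internal node whose descendant leaf set equals the subgroup."""
    for node in tree.preorder():
        if not node.is_leaf and tree.clade_leafset(node) == subgroup:
            return node
    raise ValueError("subgroup is not a clade of this tree")


def choose_positive_labels(
    tree: Tree, subgroup: frozenset[str], n: int, seed: int
) -> frozenset[str]:
    """Pick ``n`` subgroup leaves to label, spanning the subgroup root split.

    At least one leaf from each child of the subgroup ancestor is labeled
    (when n >= 2), so the minimal clade spanning the labels is the whole
    subgroup — mirroring reference enzymes scattered across a real clade.
    """
    if not (1 <= n <= len(subgroup)):
        raise ValueError("label count out of range")
    rng = np.random.default_rng([seed, 23])
    root = subgroup_root(tree, subgroup)
    sides = [sorted(tree.clade_leafset(c)) for c in root.children]
    chosen: list[str] = []
    if n >= len(sides):
        for side in sides:
            chosen.append(str(rng.choice(side)))
    remaining = sorted(set(subgroup) - set(chosen))
    extra = n - len(chosen)
    if extra > 0:
        chosen.extend(str(x) for x in rng.choice(remaining, size=extra, replace=False))
    return frozenset(chosen[:n])


def evolve_sequences(
    tree: Tree, cfg: SimulationConfig, seed: int | None = None
) -> dict[str, str]:
    """Evolve a uniform-random root sequence down the tree; returns leaf FASTA."""
    if cfg.root_length < 50:
        raise ValueError("root_length must be >= 50")
    rng = np.random.default_rng([seed if seed is not None else cfg.seed, 17])
    aas = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
    out: dict[str, str] = {}

    def mutate(seq: np.ndarray, b: float) -> np.ndarray:
        mask = rng.random(seq.size) < -np.expm1(-b)
        new = seq.copy()
        k = int(mask.sum())
        if k:
            new[mask] = (new[mask] + rng.integers(1, 20, size=k)) % 20
        return new

    def walk(node: Node, seq: np.ndarray) -> None:
        for child in node.children:
            child_seq = mutate(seq, child.length or 0.0)
            if child.is_leaf:
                out[child.name] = aas[child_seq].tobytes().decode()
            else:
                walk(child, child_seq)

    root_seq = rng.integers(0, 20, size=cfg.root_length)
    walk(tree.root, root_seq)
    return out


def expected_p_distance(branch_lengths) -> float:
    """Closed-form expected p-distance along a path of branches.

    Per branch b a site changes with probability 1 - exp(-b) to one of the 19
    other residues uniformly; composing branches gives
    p = (19/20) (1 - prod_i (1 - (20/19)(1 - exp(-b_i)))) — the 19/20 factor
    is the uniform back-substitution correction.
    """
    x = 1.0
    for b in branch_lengths:
        x *= 1.0 - (20.0 / 19.0) * (1.0 - np.exp(-b))
    return (19.0 / 20.0) * (1.0 - x)


def make_reference_table(
    sequences: dict[str, str],
    labels: dict[str, str],
    query_id: str | None = None,
    subgroup: frozenset[str] | None = None,
    clean: bool = True,
) -> list[ProteinRecord]:
    """Build a reference-annotation record set for simulated sequences.

    ``labels`` maps leaf id -> defined function; everything else becomes an
    uncharacterized "putative nitrilase". Identity to the query leaf (default:
    lexicographically first labeled leaf) is computed by global alignment.
    In clean mode a label outside the planted subgroup is an error.
    """
    unknown = set(labels) - set(sequences)
    if unknown:
        raise KeyError(f"labels for unknown leaves: {sorted(unknown)}")
    if clean and subgroup is not None:
        stray = set(labels) - set(subgroup)
        if stray:
            raise ValueError(f"labeled leaves outside the planted subgroup: {sorted(stray)}")
    if query_id is None:
        if not labels:
            raise ValueError("need labels or an explicit query_id")
        query_id = min(labels)
    query_seq = sequences[query_id]
    records = []
    for i, (leaf, seq) in enumerate(sequences.items()):
        if leaf == query_id:
            identity = 100.0
        else:
            aln, _ = pairwise_global_align(query_seq, seq)
            identity = round(percent_identity(aln), 1)
        records.append(
            ProteinRecord(
                accession=leaf,
                organism=f"Simulobacter sp. {leaf}",
                residues=seq,
                predicted_function="" if leaf in labels else "putative nitrilase",
                defined_function=labels.get(leaf, ""),
                identity_to_query=identity,
            )
        )
    return records


@dataclass
class SimulatedFamily:
    """A complete synthetic input set for one pipeline run."""

    config: SimulationConfig
    tree: Tree
    subgroup: frozenset[str]
    positives: frozenset[str]
    sequences: dict[str, str]
    records: list[ProteinRecord] = field(default_factory=list)

    @property
    def planted_candidates(self) -> frozenset[str]:
        """Uncharacterized subgroup members the pipeline should rediscover."""
        return self.subgroup - self.positives


def simulate_family(cfg: SimulationConfig) -> SimulatedFamily:
    """Tree + labels + sequences + reference table, all from ``cfg.seed``."""
    tree, subgroup = simulate_tree(cfg)
    positives = choose_positive_labels(tree, subgroup, cfg.n_labeled_positives, cfg.seed)
    sequences = evolve_sequences(tree, cfg)
    labels = {p: cfg.target_function for p in positives}
    records = make_reference_table(sequences, labels, subgroup=subgroup)
    return SimulatedFamily(cfg, tree, subgroup, positives, sequences, records)


def simulate_kinetics(
    Km: float,
    Vmax: float,
    S_grid=DEFAULT_S_GRID,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> list[KineticPoint]:
    """Michaelis-Menten rates with multiplicative Gaussian noise (sd = cv).

    Noise draws are truncated (redrawn) so every rate stays positive.
    """
    if Km <= 0 or Vmax <= 0:
        raise ValueError("Km and Vmax must be > 0")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    if not len(S_grid):
        raise ValueError("empty substrate grid")
    rng = np.random.default_rng([seed, 41])
    points = []
    for S in S_grid:
        if S <= 0:
            raise ValueError("substrate concentrations must be > 0")
        v = michaelis_menten_rate(S, Km, Vmax)
        if noise_cv > 0:
            factor = 0.0
            while factor <= 0:
                factor = 1.0 + rng.normal(0.0, noise_cv)
            v *= factor
        points.append(KineticPoint(substrate_conc=float(S), rate=float(v)))
    return points
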