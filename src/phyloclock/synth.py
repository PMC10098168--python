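"""Synthetic-data generators for every pipeline input.

Each generator is a deterministic function of its parameters and seed and
returns a machine-readable truth record, so downstream modules can be
tested end to end without any external downloads.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from phyloclock.dating import BranchData, Calibration, RootPrior, TreeIndex
from phyloclock.qc import AlignmentMatrix, FilterProfile, HitRecord
from phyloclock.rates import RateAssignment, RateModelParams, simulate_rates
from phyloclock.trees import Node, PhyloTree, TaxonAnnotation, write_annotations

__all__ = [
    "SimulationScenario",
    "simulate_time_tree",
    "simulate_branch_counts",
    "make_taxonomy_fixture",
    "make_alignment_fixture",
    "make_hits_fixture",
    "build_end_to_end_dataset",
]

_AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


@dataclass
class SimulationScenario:
    """Full specification of one synthetic dating study."""

    n_tips: int = 20
    crown_age: float = 2000.0
    birth_rate: float = 1.0
    params: RateModelParams = field(
        default_factory=lambda: RateModelParams(model="UGAM", nu=0.3, mu=1e-3)
    )
    L: int = 2000
    n_calibrations: int = 3
    calibration_rel_width: float = 0.15
    calibration_bias: Dict[str, float] = field(default_factory=dict)  # group -> Ma shift
    order_block_sizes: Tuple[int, ...] = (4, 3)
    n_hgt: int = 1
    root_prior: Optional[RootPrior] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tips < 2:
            raise ValueError("n_tips must be >= 2")
        if self.crown_age <= 0:
            raise ValueError("crown age must be > 0")
        if self.root_prior is None:
            self.root_prior = RootPrior(1.5 * self.crown_age, 0.5 * self.crown_age)


def simulate_time_tree(
    n_tips: int, crown_age: float, birth_rate: float = 1.0, seed=None
) -> PhyloTree:
    """Yule (pure-birth) tree conditioned on a tip count, with the crown
    (root) age rescaled to ``crown_age``; all tips at age 0."""
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = _as_rng(seed)
    root = Node()
    split_time = {id(root): 0.0}
    active: List[Node] = []
    for _ in range(2):
        active.append(root.add_child(Node()))
    t = 0.0
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / (birth_rate * k))
        node = active.pop(int(rng.integers(k)))
        split_time[id(node)] = t
        for _ in range(2):
            active.append(node.add_child(Node()))
    total = t + rng.exponential(1.0 / (birth_rate * n_tips))
    scale = crown_age / total

    tip_no = 0

    def assign(node: Node) -> None:
        nonlocal tip_no
        for child in node.children:
            assign(child)
        if node.is_tip:
            tip_no += 1
            node.label = f"t{tip_no}"
            node.age = 0.0
        else:
            node.age = (total - split_time[id(node)]) * scale

    assign(root)
    tree = PhyloTree(root)
    tree.set_lengths_from_ages()
    tree.validate_ages()
    return tree


def simulate_branch_counts(
    chronogram: PhyloTree, rates: RateAssignment, mu: float, L: int, seed=None
) -> BranchData:
    """Per-branch Poisson substitution counts k_b ~ Poisson(r_b*mu*dt_b*L).

    ``L = 0`` produces all-zero counts (stored with L=1 to satisfy the
    data-type invariant).
    """
    rng = _as_rng(seed)
    idx = TreeIndex(chronogram)
    counts = {}
    for i in idx.nonroot:
        node = idx.nodes[i]
        dt = node.parent.age - node.age
        r = rates.branch_rates[id(node)]
        counts[idx.node_names[i]] = int(rng.poisson(r * mu * dt * L))
    return BranchData(counts=counts, L=max(L, 1))


# ------------------------------------------------------------- taxonomy


def make_taxonomy_fixture(
    tree: PhyloTree,
    order_block_sizes: Sequence[int] = (),
    n_hgt: int = 0,
    seed=None,
) -> Tuple[Dict[str, TaxonAnnotation], dict]:
    """Plant monophyletic order-level blocks and HGT-style nestings.

    Background tips get unique values at every rank (so they can only form
    singleton clades).  Each HGT nesting labels a host clade mostly
    "Bacteria" at the domain rank with a nested minority "Eukaryota"
    subclade sharing one phylum, so the host is labeled by the bacterial
    majority under composition analysis.  Returns (annotations, truth).
    """
    rng = _as_rng(seed)
    tips = tree.tip_labels
    ann = {
        label: TaxonAnnotation(
            label=label,
            ranks={
                "genus": f"g_{label}",
                "order": f"o_{label}",
                "class": f"c_{label}",
                "phylum": f"p_{label}",
                "domain": "Bacteria",
            },
        )
        for label in tips
    }
    internal = [n for n in tree.preorder() if not n.is_tip and n.parent is not None]
    tips_below = {}
    for node in tree.postorder():
        tips_below[id(node)] = (
            [node.label] if node.is_tip else sum((tips_below[id(c)] for c in node.children), [])
        )

    used: set = set()
    truth = {"blocks": [], "hgt": []}
    for bi, size in enumerate(order_block_sizes):
        candidates = [
            n
            for n in internal
            if len(tips_below[id(n)]) == size and not used & set(tips_below[id(n)])
        ]
        if not candidates:
            raise ValueError(f"no free clade of size {size} for order block {bi}")
        node = candidates[int(rng.integers(len(candidates)))]
        members = tips_below[id(node)]
        value = f"order_block{bi}"
        for m in members:
            ann[m].ranks["order"] = value
        used |= set(members)
        truth["blocks"].append({"rank": "order", "value": value, "tips": sorted(members)})

    for hi in range(n_hgt):
        hosts = []
        for n in internal:
            members = tips_below[id(n)]
            if used & set(members) or len(members) < 4:
                continue
            for c in n.children:
                nested = tips_below[id(c)]
                if len(nested) / len(members) <= 0.33:
                    hosts.append((n, c))
        if not hosts:
            raise ValueError(f"no feasible host clade for HGT nesting {hi}")
        host, nested_node = hosts[int(rng.integers(len(hosts)))]
        members = tips_below[id(host)]
        nested = set(tips_below[id(nested_node)])
        bact_phylum = f"hgt{hi}_proteo"
        euk_phylum = f"hgt{hi}_asco"
        for m in members:
            if m in nested:
                ann[m].ranks["domain"] = "Eukaryota"
                ann[m].ranks["phylum"] = euk_phylum
            else:
                ann[m].ranks["phylum"] = bact_phylum
        used |= set(members)
        truth["hgt"].append(
            {
                "host_tips": sorted(members),
                "host_majority": "Bacteria",
                "nested_tips": sorted(nested),
                "bacterial_phylum": bact_phylum,
                "eukaryote_phylum": euk_phylum,
            }
        )
    return ann, truth


# ------------------------------------------------------------- alignment


def make_alignment_fixture(
    n_seqs: int,
    width: int,
    triad_cols: Tuple[int, int, int] = (10, 20, 30),
    n_triad_violators: int = 0,
    n_insertion_violators: int = 0,
    insertion_len: int = 20,
    seed=None,
) -> Tuple[AlignmentMatrix, dict]:
    """Alignment with conserved E/K/C catalytic columns, planted gap
    violators, and planted single-sequence insertions."""
    if n_triad_violators + n_insertion_violators > n_seqs:
        raise ValueError("more violators than sequences")
    if any(not 1 <= c <= width for c in triad_cols):
        raise ValueError("triad columns outside alignment width")
    rng = _as_rng(seed)
    ids = [f"seq{i:04d}" for i in range(n_seqs)]
    matrix = rng.choice(_AMINO_ACIDS, size=(n_seqs, width))
    for col, res in zip(triad_cols, "EKC"):
        matrix[:, col - 1] = res

    order = rng.permutation(n_seqs)
    triad_violators = sorted(ids[i] for i in order[:n_triad_violators])
    insertion_violators = sorted(
        ids[i] for i in order[n_triad_violators : n_triad_violators + n_insertion_violators]
    )
    for sid in triad_violators:
        col = int(rng.choice(triad_cols))
        matrix[ids.index(sid), col - 1] = "-"
    blocks = []
    for sid in insertion_violators:
        block = np.full((n_seqs, insertion_len), "-", dtype="U1")
        block[ids.index(sid)] = rng.choice(_AMINO_ACIDS, size=insertion_len)
        blocks.append(block)
    if blocks:
        matrix = np.hstack([matrix] + blocks)

    aln = AlignmentMatrix(ids, ["".join(row) for row in matrix])
    truth = {
        "triad_violators": triad_violators,
        "insertion_violators": insertion_violators,
        "triad_cols": list(triad_cols),
        "insertion_len": insertion_len,
    }
    return aln, truth


# ------------------------------------------------------------------ hits


def make_hits_fixture(
    n: int, profile: FilterProfile, margin: float = 2.0, seed=None
) -> Tuple[List[HitRecord], dict]:
    """Hits straddling every active threshold of ``profile`` at +/- margin,
    with truth labels for retained count and per-rule rejections."""
    if margin <= 0:
        raise ValueError("margin must be > 0")
    rng = _as_rng(seed)
    lo, hi = profile.length_window
    fail_modes = []
    if profile.min_identity > 0:
        fail_modes.append("identity")
    if profile.min_coverage > 0:
        fail_modes.append("coverage")
    if np.isfinite(profile.max_evalue):
        fail_modes.append("evalue")
    fail_modes += ["length_low", "length_high", "partial"]

    mid_len = int((lo + min(hi, lo + 400)) // 2)
    good_eval = (profile.max_evalue if np.isfinite(profile.max_evalue) else 1e-10) / 100

    hits: List[HitRecord] = []
    truth_rejections = {r: 0 for r in ("identity", "coverage", "evalue", "length", "partial")}
    retained = 0
    for i in range(n):
        mode = "pass" if rng.random() < 0.5 else fail_modes[int(rng.integers(len(fail_modes)))]
        identity = min(profile.min_identity + margin, 100.0)
        coverage = min(profile.min_coverage + margin, 100.0)
        evalue = good_eval
        length = mid_len
        partial = False
        if mode == "identity":
            identity = max(profile.min_identity - margin, 0.0)
        elif mode == "coverage":
            coverage = max(profile.min_coverage - margin, 0.0)
        elif mode == "evalue":
            evalue = profile.max_evalue * 10.0
        elif mode == "length_low":
            length = max(lo - max(1, int(round(margin))), 1)
        elif mode == "length_high":
            length = hi + max(1, int(round(margin)))
        elif mode == "partial":
            partial = True
        hits.append(
            HitRecord(
                query_id="query",
                subject_id=f"hit{i:05d}",
                organism=f"Genus{i} species{i}",
                identity=identity,
                coverage=coverage,
                evalue=evalue,
                length=length,
                partial=partial,
            )
        )
        if mode == "pass":
            retained += 1
        else:
            rule = "length" if mode.startswith("length") else mode
            truth_rejections[rule] += 1
    return hits, {"retained": retained, "rejections": truth_rejections}


# ------------------------------------------------------------ full bundle


def build_end_to_end_dataset(scenario: SimulationScenario, outdir) -> dict:
    """Write a complete pipeline input bundle and its truth manifest.

    Products: true chronogram, gene tree with substitution branch lengths,
    branch counts, taxon annotations, calibration YAML, QC fixtures
    (alignment + hit table), truth record and a manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(scenario.seed).spawn(5)
    rng_tree, rng_rates, rng_counts, rng_tax, rng_qc = (
        np.random.default_rng(s) for s in seeds
    )

    tree = simulate_time_tree(
        scenario.n_tips, scenario.crown_age, scenario.birth_rate, rng_tree
    )
    rates = simulate_rates(tree, scenario.params, rng_rates)
    data = simulate_branch_counts(
        tree, rates, scenario.params.mu, scenario.L, rng_counts
    )
    idx = TreeIndex(tree)

    # calibrations on the deepest distinct internal nodes below the root
    internal = [
        i for i in idx.internal if i != idx.root and not idx.is_tip[i]
    ]
    by_age = sorted(internal, key=lambda i: -idx.nodes[i].age)
    groups = ("plant", "animal", "fungal")
    calibrations: List[Calibration] = []
    truth_cal = []
    w = scenario.calibration_rel_width
    for ci, node_i in enumerate(by_age[: scenario.n_calibrations]):
        node = idx.nodes[node_i]
        group = groups[ci % len(groups)]
        bias = scenario.calibration_bias.get(group, 0.0)
        tip_a = _leftmost_tip(node.children[0])
        tip_b = _leftmost_tip(node.children[1])
        lo = max(node.age * (1 - w) + bias, 1.0)
        hi = max(node.age * (1 + w) + bias, lo + 1.0)
        cal = Calibration(
            name=f"cal_{group}_{ci}", tip_a=tip_a, tip_b=tip_b,
            min_age=lo, max_age=hi, group=group,
        )
        calibrations.append(cal)
        truth_cal.append(
            {
                "name": cal.name,
                "group": group,
                "true_age": node.age,
                "min_age": lo,
                "max_age": hi,
                "bias": bias,
                "tip_a": tip_a,
                "tip_b": tip_b,
            }
        )

    try:
        annotations, tax_truth = make_taxonomy_fixture(
            tree, scenario.order_block_sizes, scenario.n_hgt, rng_tax
        )
    except ValueError:
        # small/unlucky topologies may not fit the requested plantings;
        # fall back to plain unique-label taxonomy and record it
        annotations, tax_truth = make_taxonomy_fixture(tree, (), 0, rng_tax)
        tax_truth["degraded"] = True
    aln, aln_truth = make_alignment_fixture(
        n_seqs=30, width=60, n_triad_violators=3, n_insertion_violators=2,
        insertion_len=20, seed=rng_qc,
    )
    hits, hits_truth = make_hits_fixture(
        200, profile=_default_profile(), margin=2.0, seed=rng_qc
    )

    # gene tree: same topology, branch lengths = observed substitutions/site
    gene = tree.copy()
    gidx = TreeIndex(gene)
    for i in gidx.nonroot:
        node = gidx.nodes[i]
        node.length = data.counts[gidx.node_names[i]] / data.L
        node.age = None
    gidx.nodes[gidx.root].age = None

    tree.write(outdir / "chronogram.nwk")
    gene.write(outdir / "gene_tree.nwk")
    data.to_tsv(outdir / "counts.tsv")
    write_annotations(annotations, outdir / "annotations.tsv")
    aln.to_fasta(outdir / "alignment.fasta")
    from phyloclock.qc import write_hits

    write_hits(hits, outdir / "hits.tsv")
    cal_doc = {
        "root_prior": {
            "old": scenario.root_prior.old_bound,
            "young": scenario.root_prior.young_bound,
        },
        "calibrations": [
            {
                "name": c.name,
                "tip_a": c.tip_a,
                "tip_b": c.tip_b,
                "min_age": c.min_age,
                "max_age": c.max_age,
                "group": c.group,
            }
            for c in calibrations
        ],
    }
    with open(outdir / "calibrations.yaml", "w") as fh:
        yaml.safe_dump(cal_doc, fh, sort_keys=True)

    truth = {
        "seed": scenario.seed,
        "root_age": idx.nodes[idx.root].age,
        "mu": scenario.params.mu,
        "model": scenario.params.model,
        "L": data.L,
        "calibrations": truth_cal,
        "taxonomy": tax_truth,
        "alignment": aln_truth,
        "hits": hits_truth,
        "node_ages": {
            idx.node_names[i]: idx.nodes[i].age for i in idx.internal
        },
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    manifest = {
        "files": sorted(
            p.name for p in outdir.iterdir() if p.name != "manifest.json"
        ),
        "scenario": {
            "n_tips": scenario.n_tips,
            "crown_age": scenario.crown_age,
            "model": scenario.params.model,
            "mu": scenario.params.mu,
            "L": scenario.L,
            "seed": scenario.seed,
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return truth


def _default_profile() -> FilterProfile:
    from phyloclock.qc import PROFILES

    return PROFILES["nitrilase-blast"]


def _leftmost_tip(node: Node) -> str:
    while not node.is_tip:
        node = node.children[0]
    return node.label
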