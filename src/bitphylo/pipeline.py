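"""End-to-end orchestration: perturbation replicates, per-replicate
tree inference, majority-rule consensus, and the unperturbed guide
tree.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import dendropy

from . import consensus as cns
from . import distances, perturbation, scoring, trees
from .perturbation import DEFAULT_THETA
from .scoring import AlignerParams
from .sequences import SequenceSet


@dataclass
class RunConfig:
    """Everything needed to reproduce a full inference run."""

    replicates: int = 100
    theta: float = DEFAULT_THETA
    aligner: AlignerParams = field(default_factory=AlignerParams)
    overlap_form: str = "dice"
    tree_method: str = "bme_nni"
    consensus_min_freq: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.theta < 0:
            raise ValueError("theta must be >= 0 (0 = no perturbation)")


@dataclass
class RunResult:
    consensus_tree: dendropy.Tree
    guide_tree: dendropy.Tree
    distance_matrix: distances.DistanceMatrix
    replicate_trees: list[dendropy.Tree]
    replicate_rf_to_guide: list[int]
    config: RunConfig


def distances_for(seqs: SequenceSet, params: AlignerParams | None = None,
                  overlap_form: str = "dice") -> distances.DistanceMatrix:
    raw = scoring.compute_scores_internal(seqs, params)
    return distances.raw_to_distance(raw, overlap_form)


def run_pipeline(seqs: SequenceSet, config: RunConfig | None = None) -> RunResult:
    """Replicate-perturbation consensus inference plus the guide tree.

    The guide tree is inferred from the unperturbed distance matrix and
    is always strictly bifurcating; the consensus is built over
    ``config.replicates`` perturbed copies and may contain polytomies
    where support falls at or below the majority threshold.
    """
    config = config or RunConfig()
    seqs.require_min_taxa(4)
    model = perturbation.remap_matrix(theta=config.theta)

    dmat = distances_for(seqs, config.aligner, config.overlap_form)
    guide = trees.infer_tree(dmat, config.tree_method)

    replicate_sets = perturbation.make_replicates(
        seqs, model, config.replicates, config.seed)
    replicate_trees = []
    for rep in replicate_sets:
        rep_d = distances_for(rep, config.aligner, config.overlap_form)
        replicate_trees.append(trees.infer_tree(rep_d, config.tree_method))
    consensus_tree = cns.majority_consensus(
        replicate_trees, min_freq=config.consensus_min_freq)
    rf = [cns.robinson_foulds(t, guide) for t in replicate_trees]
    return RunResult(consensus_tree, guide, dmat, replicate_trees, rf, config)


def consensus_for_family(seqs: SequenceSet, theta: float,
                         replicates: int = 100, seed: int = 0,
                         tree_method: str = "bme_nni") -> dendropy.Tree:
    """Consensus tree only — the calibration inner loop."""
    config = RunConfig(replicates=replicates, theta=theta, seed=seed,
                       tree_method=tree_method)
    return run_pipeline(seqs, config).consensus_tree


def write_report(result: RunResult, out_dir: str | Path) -> None:
    """Write consensus/guide Newick, PHYLIP distances and a run report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    trees.write_newick(result.consensus_tree, out / "consensus.nwk")
    trees.write_newick(result.guide_tree, out / "guide.nwk")
    distances.write_phylip(result.distance_matrix, out / "distances.phylip")
    report = {
        "parameters": {
            **{k: v for k, v in dataclasses.asdict(result.config).items()
               if k != "aligner"},
            "aligner": dataclasses.asdict(result.config.aligner),
        },
        "n_taxa": result.distance_matrix.n,
        "replicate_rf_to_guide": result.replicate_rf_to_guide,
        "consensus_bipartitions": len(cns.bipartitions(result.consensus_tree)),
        "guide_bipartitions": len(cns.bipartitions(result.guide_tree)),
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
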