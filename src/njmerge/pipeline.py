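"""The divide-and-conquer pipeline around NJMerge.

Four steps: (1) estimate a distance matrix from gene trees (AGID) or from
a concatenated alignment (log-det); (2) compute an NJ starting tree from
that matrix and decompose it into pairwise disjoint subsets with a
centroid decomposition; (3) build a tree on each subset with the chosen
base method; (4) merge the subset trees with NJMerge guided by the same
matrix.

The serialized running time of the pipeline decomposes as

    t_P = t_D + sum_i t_T(i) + t_M

(distance estimation, per-subset tree construction, merging); the
:class:`RuntimeLedger` records each component so the parallel wall clock
can be derived from the per-subset times.

Base methods
------------
``internal:nj``
    NJ on the distance matrix restricted to the subset (hermetic).
``internal:true``
    Restriction of a supplied reference tree to the subset (yields
    constraints that agree with that tree by construction; used to study
    the idealized regime).
A shell command template with ``{taxa}`` and ``{output}`` placeholders
    runs an external subset-tree method; it must write Newick to
    ``{output}``.
"""

from __future__ import annotations

import subprocess
import tempfile
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional, Sequence

from .compat import agrees_with
from .decompose import centroid_decompose
from .distances import DistanceMatrix, agid_matrix, logdet_matrix
from .errors import ExternalMethodError, NJMergeError, TreeError
from .merge import MergeResult, njmerge
from .nj import nj_tree
from .tree import Alignment, PhyloTree, parse_newick, restrict

__all__ = ["PipelineConfig", "RuntimeLedger", "PipelineInputs", "run_pipeline",
           "aggregate_runtime"]


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    ``max_subset_size`` defaults to 30, the value used for ~100-taxon
    problems; ~1000-taxon problems use 120.
    """

    distance: Literal["agid", "logdet"] = "agid"
    max_subset_size: int = 30
    base_method: str = "internal:nj"
    mode: Literal["pairwise", "groupwise"] = "pairwise"
    iterations: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.distance not in ("agid", "logdet"):
            raise NJMergeError(f"unknown distance method: {self.distance!r}")
        if self.iterations < 1:
            raise NJMergeError("iterations must be >= 1")


@dataclass
class PipelineInputs:
    gene_trees: Optional[Sequence[PhyloTree]] = None
    alignment: Optional[Alignment] = None
    reference_tree: Optional[PhyloTree] = None  # for internal:true


@dataclass
class RuntimeLedger:
    """Per-component timings (seconds) of one pipeline run."""

    t_distance: Optional[float] = None
    t_subtrees: list[float] = field(default_factory=list)
    t_merge: Optional[float] = None

    @property
    def n_subsets(self) -> int:
        return len(self.t_subtrees)


def aggregate_runtime(ledger: RuntimeLedger) -> float:
    """Serialized total: t_D + sum_i t_T(i) + t_M."""
    if ledger.t_distance is None or ledger.t_merge is None:
        raise NJMergeError("runtime ledger is missing a component")
    return ledger.t_distance + sum(ledger.t_subtrees) + ledger.t_merge


def _estimate_matrix(config: PipelineConfig, inputs: PipelineInputs) -> DistanceMatrix:
    if config.distance == "agid":
        if not inputs.gene_trees:
            raise NJMergeError("AGID distances require gene trees")
        return agid_matrix(list(inputs.gene_trees))
    if inputs.alignment is None:
        raise NJMergeError("log-det distances require an alignment")
    return logdet_matrix(inputs.alignment)


def _subset_tree(
    config: PipelineConfig,
    inputs: PipelineInputs,
    D: DistanceMatrix,
    subset: frozenset[str],
) -> PhyloTree:
    method = config.base_method
    if len(subset) <= 2:
        # no topology to estimate: build the trivial tree directly
        from .tree import Node

        if len(subset) == 1:
            return PhyloTree(Node(next(iter(subset))), rooted=False)
        hub = Node()
        for lab in sorted(subset):
            hub.add_child(Node(lab))
        return PhyloTree(hub, rooted=False)
    if method == "internal:nj":
        return nj_tree(D.submatrix(sorted(subset)))
    if method == "internal:true":
        if inputs.reference_tree is None:
            raise NJMergeError("internal:true base method needs a reference tree")
        return restrict(inputs.reference_tree, subset)
    return _external_tree(method, subset)


def _external_tree(template: str, subset: frozenset[str]) -> PhyloTree:
    """Run an external subset-tree command built from a template with
    ``{taxa}`` (file of one taxon per line) and ``{output}`` placeholders."""
    with tempfile.TemporaryDirectory() as tmp:
        taxa_file = Path(tmp) / "taxa.txt"
        out_file = Path(tmp) / "subtree.nwk"
        taxa_file.write_text("\n".join(sorted(subset)) + "\n")
        cmd = template.format(taxa=taxa_file, output=out_file)
        proc = subprocess.run(cmd, shell=True, capture_output=True, text=True)
        if proc.returncode != 0:
            raise ExternalMethodError(
                f"subset-tree command failed on {sorted(subset)[:4]}...: "
                f"{proc.stderr.strip()[:200]}"
            )
        try:
            tree = parse_newick(out_file.read_text())
        except (OSError, NJMergeError) as exc:
            raise ExternalMethodError(
                f"unusable output for subset {sorted(subset)[:4]}...: {exc}"
            ) from exc
    if tree.leaf_labels() != subset:
        raise TreeError("external subset tree is not on the requested taxa")
    return tree


def run_pipeline(
    config: PipelineConfig, inputs: PipelineInputs
) -> tuple[PhyloTree, RuntimeLedger, MergeResult]:
    """Execute the four pipeline steps and return the merged tree, the
    runtime ledger, and the merge result (join log, proposal ranks).

    With ``iterations > 1`` the merged tree of one round seeds the next
    round's decomposition (the matrix is estimated once).
    """
    ledger = RuntimeLedger()
    t0 = time.perf_counter()
    D = _estimate_matrix(config, inputs)
    ledger.t_distance = time.perf_counter() - t0

    start = nj_tree(D)
    result: Optional[MergeResult] = None
    for _ in range(config.iterations):
        decomposition = centroid_decompose(start, config.max_subset_size)
        forest = []
        ledger.t_subtrees = []
        for subset in decomposition.subsets:
            t0 = time.perf_counter()
            sub = _subset_tree(config, inputs, D, subset)
            ledger.t_subtrees.append(time.perf_counter() - t0)
            if sub.leaf_labels() != subset:
                raise TreeError("subset tree leaf set differs from its subset")
            if config.base_method == "internal:true":
                assert agrees_with(sub, inputs.reference_tree)
            if len(sub) >= 4:
                forest.append(sub)
        t0 = time.perf_counter()
        result = njmerge(forest, D, mode=config.mode)
        ledger.t_merge = time.perf_counter() - t0
        start = result.tree
    assert result is not None
    return result.tree, ledger, result
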