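"""End-to-end pipeline: alignments -> joint structure report.

Stages: read and pair the alignments; estimate (or load) trees; score each
part and fix its reliable partial structure (Step 1); constrained
expected-accuracy scoring of the concatenation (Step 2); decode, re-add
the partial structures and render (assembly).  Deterministic given the
configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .assemble import JointStructure, final_decode, render
from .evoscfg import inside_outside
from .msa_io import AlignmentPair, concatenate, pair_taxa, read_alignment
from .params import ParameterSet, Params, default_parameter_set, load_parameter_set
from .phylo import PhyloTree, estimate_tree, read_tree
from .scoring import combine_reliabilities
from .step1 import _Ctx, PartialStructure, extend_stems, select_partial
from .step2 import Step2Reliabilities, run_step2
from .thermo import EnergyModel, partition

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run (mirrors the CLI flags)."""

    aln1_path: str = ""
    aln2_path: str = ""
    fmt: str = "auto"
    params: Params = field(default_factory=Params)
    tree_path: str | None = None
    param_asset: str | None = None
    pairing_policy: str = "exact_id"
    out_path: str | None = None
    gap_filter: float | None = None
    seed: int | None = None
    verbosity: int = 0

    def header(self) -> str:
        p = self.params
        return (
            "#=GF CC config "
            f"delta={p.delta} gamma={p.gamma} alpha={p.alpha} beta={p.beta} "
            f"delta_step={p.delta_step} evo={p.evo} eq15={p.eq15_mode} "
            f"isolated={p.allow_isolated} gamma_agg={p.gamma_agg} "
            f"extend={p.extend_stems} policy={self.pairing_policy}"
        )


@dataclass
class PipelineResult:
    joint: JointStructure
    report: str
    partials: tuple[PartialStructure, PartialStructure]
    rel2: Step2Reliabilities
    trees: tuple


def score_part(
    aln, tree, models: ParameterSet | None, params: Params,
    energy: EnergyModel, part: int,
):
    """Step-1 scoring and partial-structure fixing for one alignment."""
    ctx = _Ctx(aln, tree, models, energy, params)
    evo = (
        inside_outside(aln, tree, models, emissions=ctx.emissions)
        if params.evo
        else None
    )
    rel = combine_reliabilities(
        evo, ctx.thermo_bases, aln, params.beta, params.alpha
    )
    partial = select_partial(
        rel, aln, tree, models, params, energy, part=part, ctx=ctx
    )
    if params.extend_stems:
        partial = extend_stems(
            partial, rel, params, aln, tree, models, energy, ctx=ctx
        )
    return rel, partial


def run_pipeline_on_pair(
    pair: AlignmentPair,
    params: Params | None = None,
    models: ParameterSet | None = None,
    energy: EnergyModel | None = None,
    trees: tuple | None = None,
    gap_filter: float | None = None,
    config_header: str | None = None,
) -> PipelineResult:
    """Run the two-step prediction on an already-paired alignment pair.

    ``trees`` optionally supplies (tree1, tree2, joint tree); missing
    entries are estimated from the corresponding alignment.
    """
    params = params or Params()
    if params.evo and models is None:
        models = default_parameter_set()
    energy = energy or EnergyModel(allow_isolated=params.allow_isolated)

    tree1 = tree2 = tree_joint = None
    if params.evo:
        t1, t2, tj = trees if trees is not None else (None, None, None)
        tree1 = t1 or estimate_tree(pair.aln1)
        tree2 = t2 or estimate_tree(pair.aln2)
        tree_joint = tj or estimate_tree(
            concatenate(pair, "evo").to_alignment(linker_as="N")
        )

    log.info("step 1: part 1 (%d seqs, %d cols)", pair.aln1.n_seqs, pair.aln1.length)
    rel1, partial1 = score_part(pair.aln1, tree1, models, params, energy, 1)
    log.info("step 1: part 2 (%d seqs, %d cols)", pair.aln2.n_seqs, pair.aln2.length)
    rel2_part, partial2 = score_part(pair.aln2, tree2, models, params, energy, 2)

    log.info(
        "step 2: cofolding with |sigma1|=%d (delta=%.2f), |sigma2|=%d (delta=%.2f)",
        len(partial1.pairs), partial1.delta_used,
        len(partial2.pairs), partial2.delta_used,
    )
    rel2 = run_step2(
        pair, (partial1, partial2), tree_joint, models, energy, params
    )
    joint = final_decode(rel2, (partial1, partial2), params)
    report = render(joint, pair, gap_filter)
    if config_header:
        lines = report.splitlines()
        lines.insert(1, config_header)
        report = "\n".join(lines) + "\n"
    return PipelineResult(
        joint, report, (partial1, partial2), rel2, (tree1, tree2, tree_joint)
    )


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the pipeline from input files per the configuration."""
    params = config.params
    aln1 = read_alignment(config.aln1_path, config.fmt)
    aln2 = read_alignment(config.aln2_path, config.fmt)
    pair = pair_taxa(
        aln1, aln2, config.pairing_policy, min_taxa=2 if params.evo else 1
    )
    models = (
        load_parameter_set(config.param_asset)
        if config.param_asset
        else (default_parameter_set() if params.evo else None)
    )
    trees = None
    if config.tree_path and params.evo:
        taxa1 = [a for a, _ in pair.taxon_map]
        user = read_tree(config.tree_path, None)
        # a single user tree (over the shared taxa) overrides all estimates
        trees = (user, user, user)
    result = run_pipeline_on_pair(
        pair, params, models,
        EnergyModel(allow_isolated=params.allow_isolated),
        trees, config.gap_filter, config.header(),
    )
    if config.out_path:
        with open(config.out_path, "w") as fh:
            fh.write(result.report)
    return result
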