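"""End-to-end biomarker discovery convenience wrapper.

Chains the stages a full run performs on one cohort: per-gene cutpoint
ranking, the four-selector consensus, correlation pruning, panel
assembly, the exhaustive (family × subset) LOOCV search over the
panel's strongest genes, and the frequency consensus over the top-F1
models.  Each stage is the corresponding module operation with the
pipeline's canonical defaults; any intermediate is available on the
returned result for inspection.

The search stage enumerates subsets of the top ``search_genes`` genes
of the panel (default 8, i.e. 247 subsets per family) rather than the
full panel: the full diagnostic configuration (16 + forced genes, about
65,000 subsets per family) is a cluster-scale computation by design.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .containers import ExpressionMatrix, SampleAnnotation
from .feature_select import (
    SelectionVote,
    assemble_panel,
    consensus_select,
    correlation_prune,
    run_selectors,
)
from .model_search import LeaderboardEntry, PanelReport, consensus_genes, enumerate_search
from .thresholding import rank_genes


@dataclass
class DiscoveryResult:
    """All intermediates of one discovery run."""

    ranked: pd.DataFrame
    votes: list[SelectionVote]
    eligible: set[str]
    pruned: set[str]
    panel: list[str]
    entries: list[LeaderboardEntry] = field(default_factory=list)
    consensus: PanelReport | None = None

    @property
    def selected(self) -> list[str]:
        return [] if self.consensus is None else self.consensus.selected


def discovery_pipeline(
    matrix: ExpressionMatrix,
    ann: SampleAnnotation,
    seed: int = 0,
    top_n: int = 16,
    f1_min_panel: float = 0.7,
    min_votes: int = 2,
    r_max: float = 0.9,
    forced: Sequence[str] = (),
    search_genes: int = 8,
    families: Sequence[str] = ("linear_svm",),
    f1_min_consensus: float = 0.96,
    freq_cutoff: float = 0.5,
    run_search: bool = True,
) -> DiscoveryResult:
    """Run rank → select → prune → panel → search → consensus on a cohort."""
    ranked = rank_genes(matrix, ann)
    votes = run_selectors(matrix, ann, k=min(2 * top_n, matrix.n_genes), seed=seed)
    eligible = consensus_select(votes, min_votes=min_votes)
    priority = dict(zip(ranked["gene_id"], ranked["f1"]))
    pruned = correlation_prune(matrix, eligible & set(priority), r_max=r_max,
                               priority=priority)
    panel = assemble_panel(ranked, pruned, f1_min=f1_min_panel, top_n=top_n,
                           forced=forced)
    result = DiscoveryResult(ranked=ranked, votes=votes, eligible=eligible,
                             pruned=pruned, panel=panel)
    if run_search and len(panel) >= 2:
        search_panel = panel[: min(search_genes, len(panel))]
        result.entries = enumerate_search(matrix, ann, search_panel,
                                          families=families, seed=seed)
        result.consensus = consensus_genes(result.entries, f1_min=f1_min_consensus,
                                           freq_cutoff=freq_cutoff)
    return result
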