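"""Ranking and testing of a-priori supertree hypotheses.

A hypothesis is a candidate supertree spanning (at least) the union taxon
set of the inputs.  Hypotheses are ranked by total log-likelihood; pairs
are compared with a winning-sites (sign) test on per-input-tree
log-likelihoods; and the per-input-tree log-likelihood matrix can be
exported in CONSEL's ``.mt`` format, with input trees playing the role of
sites, so CONSEL's RELL bootstrap resamples trees and yields KH/SH/AU
p-values for the hypothesis set.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

from scipy.stats import binomtest

from .likelihood import ScoreBreakdown, SteelRodrigoModel, score_supertree
from .trees import InputTreeSet, Tree, TreeError

__all__ = [
    "HypothesisSet",
    "RankedHypothesis",
    "WinningSitesResult",
    "score_hypotheses",
    "rank_hypotheses",
    "winning_sites_test",
    "winning_sites_all_pairs",
    "export_consel_matrix",
    "read_consel_matrix",
]


@dataclass
class HypothesisSet:
    """Named hypothesis supertrees with their score breakdowns.

    Names, trees and scores are parallel lists, all scored against one
    input-tree set and model.
    """

    names: Tuple[str, ...]
    trees: Tuple[Tree, ...]
    scores: Tuple[ScoreBreakdown, ...]

    def __len__(self) -> int:
        return len(self.names)


@dataclass(frozen=True)
class RankedHypothesis:
    rank: int
    name: str
    total_log_likelihood: float
    tied: bool


@dataclass(frozen=True)
class WinningSitesResult:
    """Sign-test tally: per-input-tree wins for each hypothesis.

    ``wins_a + wins_b + ties`` equals the number of input trees.  The
    p-value is the exact two-sided binomial probability of a split at
    least as extreme as (wins_a, wins_b) under Binomial(wins_a+wins_b, ½);
    ties are excluded from the trial count, and an all-ties comparison is
    assigned p = 1 by convention.
    """

    wins_a: int
    wins_b: int
    ties: int
    p_value: float


def score_hypotheses(names: Sequence[str], trees: Sequence[Tree],
                     inputs: InputTreeSet,
                     model: SteelRodrigoModel = SteelRodrigoModel()) -> HypothesisSet:
    """Score each hypothesis tree against the inputs."""
    if len(names) != len(trees):
        raise ValueError("names and trees must be parallel")
    scores = tuple(score_supertree(t, inputs, model) for t in trees)
    return HypothesisSet(tuple(names), tuple(trees), scores)


def rank_hypotheses(hyps: HypothesisSet) -> List[RankedHypothesis]:
    """Hypotheses sorted by total log-likelihood, best first.

    Equal totals share the smaller rank and are flagged as tied
    (competition ranking: totals (-5, -5, -9) rank 1, 1, 3).
    """
    order = sorted(range(len(hyps)),
                   key=lambda i: -hyps.scores[i].total_log_likelihood)
    totals = [hyps.scores[i].total_log_likelihood for i in order]
    out: List[RankedHypothesis] = []
    for pos, i in enumerate(order):
        rank = next(p for p, t in enumerate(totals)
                    if abs(t - totals[pos]) <= 1e-9) + 1
        tied = sum(1 for t in totals if abs(t - totals[pos]) <= 1e-9) > 1
        out.append(RankedHypothesis(rank, hyps.names[i], totals[pos], tied))
    return out


def winning_sites_test(hyp_a: Tree, hyp_b: Tree, inputs: InputTreeSet,
                       model: SteelRodrigoModel = SteelRodrigoModel()
                       ) -> WinningSitesResult:
    """Winning-sites comparison of two hypothesis supertrees.

    Each input tree votes for the hypothesis with the strictly higher
    tree-wise log-likelihood (under the default model, the smaller RF
    distance); equal values are ties.
    """
    a = score_supertree(hyp_a, inputs, model).per_tree
    b = score_supertree(hyp_b, inputs, model).per_tree
    wins_a = wins_b = ties = 0
    for ra, rb in zip(a, b):
        if ra.log_likelihood > rb.log_likelihood + 1e-12:
            wins_a += 1
        elif rb.log_likelihood > ra.log_likelihood + 1e-12:
            wins_b += 1
        else:
            ties += 1
    n = wins_a + wins_b
    p = 1.0 if n == 0 else float(binomtest(wins_a, n, 0.5).pvalue)
    return WinningSitesResult(wins_a, wins_b, ties, p)


def winning_sites_all_pairs(hyps: HypothesisSet, inputs: InputTreeSet,
                            model: SteelRodrigoModel = SteelRodrigoModel()
                            ) -> List[Tuple[str, str, WinningSitesResult]]:
    """Winning-sites tests for every unordered pair of hypotheses."""
    out = []
    for i, j in itertools.combinations(range(len(hyps)), 2):
        res = winning_sites_test(hyps.trees[i], hyps.trees[j], inputs, model)
        out.append((hyps.names[i], hyps.names[j], res))
    return out


def export_consel_matrix(hyps: HypothesisSet, path,
                         names_path=None) -> None:
    """Write per-input-tree log-likelihoods in CONSEL ``.mt`` format.

    First line: number of hypotheses and number of sites (input trees);
    then one whitespace-separated row of per-input-tree log-likelihoods
    per hypothesis, in input order and at a fixed six-decimal format.
    Hypothesis names go to a sidecar index->name mapping (default
    ``<path>.names.tsv``).
    """
    if len(hyps) < 2:
        raise ValueError("CONSEL export needs at least 2 hypotheses")
    n_sites = len(hyps.scores[0].per_tree)
    with open(path, "w") as fh:
        fh.write(f"{len(hyps)} {n_sites}\n")
        for bd in hyps.scores:
            fh.write(" ".join(f"{r.log_likelihood:.6f}" for r in bd.per_tree))
            fh.write("\n")
    names_path = names_path if names_path is not None else f"{path}.names.tsv"
    with open(names_path, "w") as fh:
        for i, name in enumerate(hyps.names):
            fh.write(f"{i + 1}\t{name}\n")


def read_consel_matrix(path) -> List[List[float]]:
    """Re-read a ``.mt`` file, validating its structure."""
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError("malformed .mt header")
        n_hyps, n_sites = int(header[0]), int(header[1])
        rows = []
        for line in fh:
            if not line.strip():
                continue
            row = [float(x) for x in line.split()]
            if len(row) != n_sites:
                raise ValueError(
                    f"row {len(rows)} has {len(row)} entries, expected {n_sites}")
            rows.append(row)
    if len(rows) != n_hyps:
        raise ValueError(f"expected {n_hyps} rows, found {len(rows)}")
    return rows
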