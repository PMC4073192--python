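"""The exponential supertree likelihood of Steel and Rodrigo.

An input tree T' on taxa Y is modelled as a subsample of the supertree T:
prune T to Y and measure the Robinson--Foulds distance d between the
pruned supertree and T'.  The probability of observing T' is

    P(T' | T, Y) = alpha * exp(-beta * d)

so the per-tree log-likelihood is ln(alpha) - beta*d, and the supertree's
log-likelihood is the sum over input trees.  Phylogenetic error decays
exponentially in d.  alpha is a normalising constant that in principle
depends on the size of Y; following Bryant and Steel it is approximated
by alpha = 1 (valid for small beta), which shifts every supertree's score
by the same amount and leaves all rankings unchanged.  beta, the weight
expressing the quantity and quality of the data behind the input trees,
is likewise fixed at 1, so under defaults the total log-likelihood is
exactly minus the sum of RF distances.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Tuple

from .splits import restrict_split_keys, robinson_foulds, splits_of
from .trees import InputTreeSet, Tree, TreeError, prune_to_taxa

__all__ = [
    "SteelRodrigoModel",
    "PerTreeScore",
    "ScoreBreakdown",
    "tree_wise_log_likelihood",
    "score_supertree",
]


@dataclass(frozen=True)
class SteelRodrigoModel:
    """Parameters (alpha, beta) of the exponential likelihood.

    alpha > 0 is the normalising constant, beta > 0 the data-quality
    weight; the defaults alpha = 1, beta = 1 are the approximation the
    method is defined with.
    """

    alpha: float = 1.0
    beta: float = 1.0

    def __post_init__(self):
        if not self.alpha > 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")
        if not self.beta > 0:
            raise ValueError(f"beta must be positive, got {self.beta}")

    @property
    def log_alpha(self) -> float:
        return math.log(self.alpha)


@dataclass(frozen=True)
class PerTreeScore:
    """One input tree's contribution: RF distance and log-likelihood."""

    index: int
    n_overlap: int
    distance: int
    log_likelihood: float


@dataclass(frozen=True)
class ScoreBreakdown:
    """Per-input-tree distances/log-likelihoods and their total.

    ``per_tree`` order matches the input-tree order; the total is the sum
    of the per-tree log-likelihoods (under the default model, exactly
    minus the summed RF distances).
    """

    per_tree: Tuple[PerTreeScore, ...]
    total_log_likelihood: float

    @property
    def total_distance(self) -> int:
        return sum(r.distance for r in self.per_tree)


def tree_wise_log_likelihood(supertree: Tree, input_tree: Tree,
                             model: SteelRodrigoModel = SteelRodrigoModel()) -> float:
    """ln alpha - beta*d for one input tree, by explicit prune-then-RF.

    The supertree is pruned to the input tree's taxon set and d is the RF
    distance between the pruned supertree and the input tree.  The input
    tree's taxa must all occur in the supertree.
    """
    orphans = input_tree.taxa - supertree.taxa
    if orphans:
        raise TreeError(
            f"input tree has taxa absent from the supertree: {sorted(orphans)}")
    pruned = prune_to_taxa(supertree, input_tree.taxa)
    d = robinson_foulds(pruned, input_tree)
    return model.log_alpha - model.beta * d


def score_supertree(supertree: Tree, inputs: InputTreeSet,
                    model: SteelRodrigoModel = SteelRodrigoModel()) -> ScoreBreakdown:
    """Log-likelihood of a supertree given a set of input trees.

    Equivalent to summing :func:`tree_wise_log_likelihood` over the input
    trees, but computed by restricting the supertree's split set to each
    input tree's taxa (the splits of a pruned tree are exactly the
    non-degenerate restrictions of the original splits), which makes
    repeated scoring during tree search cheap.
    """
    st_taxa = supertree.taxa
    st_pairs = tuple((s.side_a, s.side_b) for s in splits_of(supertree))
    records = []
    total = 0.0
    small = []
    for idx, (taxa_i, _pairs_i, keys_i) in enumerate(inputs.split_profiles()):
        missing = taxa_i - st_taxa
        if missing:
            raise TreeError(
                f"input tree {idx} has taxa missing from the supertree: "
                f"{sorted(missing)}")
        if len(taxa_i) < 4:
            small.append(idx)
        restricted = restrict_split_keys(st_pairs, taxa_i)
        d = len(restricted ^ keys_i)
        ll = model.log_alpha - model.beta * d
        records.append(PerTreeScore(idx, len(taxa_i), d, ll))
        total += ll
    if small:
        warnings.warn(
            f"input trees {small} have fewer than 4 taxa and carry no "
            "informative splits (their distance is always 0)",
            stacklevel=2)
    return ScoreBreakdown(tuple(records), total)


def _overlap_total(st_pairs, st_taxa, profiles, model: SteelRodrigoModel) -> float:
    """Score a partial supertree against inputs restricted to shared taxa.

    Used by stepwise addition, where the growing tree does not yet span
    the union taxon set: both the supertree and each input tree are
    restricted to their overlap.  On a full supertree this coincides with
    :func:`score_supertree`.
    """
    total = 0.0
    for taxa_i, pairs_i, keys_i in profiles:
        overlap = st_taxa & taxa_i
        if len(overlap) < 4:
            total += model.log_alpha
            continue
        if overlap == taxa_i:
            r_in = keys_i
        else:
            r_in = restrict_split_keys(pairs_i, overlap)
        r_st = restrict_split_keys(st_pairs, overlap)
        total += model.log_alpha - model.beta * len(r_st ^ r_in)
    return total
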