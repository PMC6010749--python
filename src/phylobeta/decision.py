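"""Bayes-decision evidence bands for posterior slopes.

Each node's slope draws are reduced to a tail probability p — the
posterior mass on the minority sign, i.e. the probability of rejecting
the lack of effect — and mapped to one of four fixed evidence bands:

    p < 0.05          very strong
    0.05 <= p < 0.15  strong
    0.15 <= p < 0.30  acceptable
    p >= 0.30         little evidence

Boundaries are closed on the left: p = 0.05 is "strong", p = 0.30 is
"little evidence".  The same machinery applied to a star tree with the
root slope clamped at its prior mean gives the "no phylogeny" comparator
(independent per-taxon Bayesian logistic regressions), so fits with and
without phylogenetic pooling can be contrasted taxon by taxon.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import HyperParams, OccurrenceData
from .sampler import McmcConfig, PosteriorSamples, sample_posterior
from .trees import Node, ROOT_PARENT, Topology

__all__ = [
    "CATEGORIES",
    "DecisionReport",
    "tail_probability",
    "decision_category",
    "make_report",
    "compare_models",
    "star_topology",
    "fit_plain",
]

#: evidence bands, weakest to strongest
CATEGORIES = ("little_evidence", "acceptable", "strong", "very_strong")

_BANDS = ((0.05, "very_strong"), (0.15, "strong"), (0.30, "acceptable"))


def tail_probability(draws, side: str = "two_sided") -> float:
    """Posterior probability of rejecting the lack of effect.

    Two-sided (default): the minority-sign posterior mass,
    min(P(beta > 0), P(beta < 0)), in [0, 0.5]; draws exactly zero are
    split evenly between the sides.  One-sided variants return the mass
    opposing the named sign.
    """
    d = np.asarray(draws, dtype=float)
    if d.size == 0:
        raise ValueError("tail_probability needs at least one draw")
    frac_pos = float(np.mean(d > 0) + 0.5 * np.mean(d == 0))
    if side == "two_sided":
        return min(frac_pos, 1.0 - frac_pos)
    if side == "positive":
        return 1.0 - frac_pos
    if side == "negative":
        return frac_pos
    raise ValueError(f"unknown side {side!r}")


def decision_category(p: float) -> str:
    """Map a tail probability to its evidence band (left-closed bands)."""
    if not 0.0 <= p <= 0.5:
        raise ValueError(f"tail probability {p} outside [0, 0.5]")
    for bound, cat in _BANDS:
        if p < bound:
            return cat
    return "little_evidence"


@dataclass
class DecisionReport:
    """Per-node slope summary: posterior mean and variance, sign of the
    mean, tail probability, and evidence band."""

    table: pd.DataFrame  # columns: node, taxon, mean, variance, sign, p, category

    def row(self, taxon: str) -> pd.Series:
        hit = self.table[self.table["taxon"] == taxon]
        if hit.empty:
            raise KeyError(f"no taxon {taxon!r} in report")
        return hit.iloc[0]

    def leaf_table(self) -> pd.DataFrame:
        return self.table[self.table["taxon"] != ""].reset_index(drop=True)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def make_report(samples: PosteriorSamples, side: str = "two_sided") -> DecisionReport:
    """Summarize every node's slope draws into the evidence table."""
    topo = samples.topology
    rows = []
    for i in topo.node_ids:
        draws = samples.flat(f"beta[{i}]")
        mean = float(draws.mean())
        p = tail_probability(draws, side=side)
        rows.append(
            {
                "node": i,
                "taxon": topo.label(i),
                "mean": mean,
                "variance": float(draws.var(ddof=1)),
                "sign": "+" if mean >= 0 else "-",
                "p": p,
                "category": decision_category(p),
            }
        )
    return DecisionReport(pd.DataFrame(rows))


def compare_models(
    report_phylo: DecisionReport, report_plain: DecisionReport
) -> pd.DataFrame:
    """Per-taxon contrast of the fits with and without phylogeny.

    Returns a table of (taxon, category_without, category_with, change,
    sign_flip): ``change`` is "improved" when the phylogenetic fit lands
    in a stronger band, "weakened" when weaker; a sign flip of the
    posterior-mean slope is flagged regardless of band.
    """
    taxa_p = set(report_phylo.leaf_table()["taxon"])
    taxa_q = set(report_plain.leaf_table()["taxon"])
    if taxa_p != taxa_q:
        raise ValueError(f"taxon sets differ: {sorted(taxa_p ^ taxa_q)}")
    rows = []
    for taxon in sorted(taxa_p):
        with_ = report_phylo.row(taxon)
        without = report_plain.row(taxon)
        delta = CATEGORIES.index(with_["category"]) - CATEGORIES.index(
            without["category"]
        )
        rows.append(
            {
                "taxon": taxon,
                "category_without": without["category"],
                "category_with": with_["category"],
                "change": (
                    "improved" if delta > 0 else "weakened" if delta < 0 else "no change"
                ),
                "sign_flip": with_["sign"] != without["sign"],
            }
        )
    return pd.DataFrame(rows)


def star_topology(labels) -> Topology:
    """A rootward-unstructured tree: every taxon hangs off the root."""
    labels = list(labels)
    nodes = [Node(id=1, parent_id=ROOT_PARENT, label="")]
    for k, lb in enumerate(labels):
        nodes.append(Node(id=k + 2, parent_id=1, label=lb))
    return Topology(nodes)


def fit_plain(
    data: OccurrenceData,
    h: HyperParams | None = None,
    cfg: McmcConfig | None = None,
    center_covariate: bool = False,
) -> PosteriorSamples:
    """Fit the no-phylogeny comparator: the same sampler on a star tree
    with the root slope clamped at its prior mean, so each taxon's slope
    prior is independent — ordinary Bayesian logistic regression per
    taxon under identical decision rules."""
    topo = star_topology(data.taxon_ids)
    return sample_posterior(
        data,
        topo,
        h,
        cfg,
        center_covariate=center_covariate,
        sample_root=False,
    )
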