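"""Reaction rate-potential fold-changes and bootstrap ranking scores.

The rate potential of a reaction is modelled mass-action style as
``r = k [p] * prod_i [A_i]^m_i / prod_j [B_j]^m_j`` with enzyme activity [p],
substrates A, products B and approximate stoichiometric exponents m in
{1, 2}. Assuming the catalytic rate coefficient k is unchanged between the
reference and test states, the log2 fold-change of the rate potential is the
linear combination

    log2FC(r) = log2FC(p) + sum_i m_i * log2FC(A_i) - sum_j m_j * log2FC(B_j)

over the *measured* substrates and products (unmeasured slots contribute 0).
A positive log2FC(r) means the reaction would have to consume substrates
faster to restore the reference balance.

Significance is ranked against a bootstrap null: each measured metabolite
slot is refilled with a fold-change drawn uniformly with replacement from
the pool of all measured metabolite fold-changes (and the enzyme slot from
the pool of enzyme fold-changes), preserving the reaction's topology. The
ranking score is the add-one-corrected fraction of null draws whose absolute
value reaches the observed one, so scores lie in (0, 1].
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .network import Reaction, ReactionNetwork
from .preprocess import REFERENCE, TEST, AbundanceMatrix

__all__ = [
    "ReactionPotentialResult",
    "reaction_enzyme_log2fc",
    "select_testable_reactions",
    "reaction_log2fc",
    "compute_reaction_potentials",
    "bootstrap_ranking_scores",
    "call_significant_reactions",
    "results_to_frame",
]


@dataclass(frozen=True)
class ReactionPotentialResult:
    """Per-reaction estimate with its additive component breakdown.

    ``breakdown`` holds (label, contribution) pairs whose sum is
    ``log2fc_r``: one ``enzyme`` term, ``substrate:<id>`` terms
    (+m * log2FC) and ``product:<id>`` terms (-m * log2FC).
    """

    reaction_id: str
    log2fc_r: float
    breakdown: tuple[tuple[str, float], ...]
    n_substrates_measured: int
    n_products_measured: int
    n_enzymes_measured: int
    substrate_exponents: tuple[int, ...]
    product_exponents: tuple[int, ...]
    ranking_score: float = float("nan")
    significant: bool = False

    @property
    def direction(self) -> str:
        if self.log2fc_r > 0:
            return "up"
        if self.log2fc_r < 0:
            return "down"
        return "none"


def _fc_series(table: pd.DataFrame | pd.Series) -> pd.Series:
    if isinstance(table, pd.Series):
        return table
    return table["log2FC"]


def reaction_enzyme_log2fc(
    net: ReactionNetwork,
    enzyme_activity: AbundanceMatrix,
    pseudo_count: float = 1.0,
) -> pd.DataFrame:
    """Per-reaction enzyme log2 fold-change from the enzyme-activity matrix.

    When a reaction lists several enzymes their activities are summed per
    sample before the fold-change is taken (they are treated as isoenzymes at
    the reaction level), then log2(x + pseudo_count) group means are
    differenced. Reactions with no measured enzyme are absent from the
    output. ``enzyme_activity`` must be on the linear (pre-log) scale.
    """
    if enzyme_activity.state == "log2":
        raise ValueError("reaction_enzyme_log2fc expects linear-scale enzyme activities")
    act = enzyme_activity.data
    ref_cols = enzyme_activity.samples_in(REFERENCE)
    test_cols = enzyme_activity.samples_in(TEST)
    rows = {}
    for rid, rxn in net.reactions.items():
        present = [e for e in rxn.enzymes if e in act.index]
        if not present:
            continue
        total = act.loc[present].sum(axis=0)
        logt = np.log2(total + pseudo_count)
        rows[rid] = {
            "log2FC": float(logt[test_cols].mean() - logt[ref_cols].mean()),
            "n_enzymes_measured": len(present),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "reaction_id"
    if out.empty:
        out = pd.DataFrame(columns=["log2FC", "n_enzymes_measured"])
    return out


def select_testable_reactions(
    net: ReactionNetwork,
    metab_fc: pd.DataFrame | pd.Series,
    enzyme_fc: pd.DataFrame | pd.Series | None,
    allow_missing_enzyme: bool = False,
) -> list[str]:
    """Reactions with >= 1 measured substrate, >= 1 measured product, and a
    measured enzyme (the expressed-reaction condition).

    ``enzyme_fc`` is the per-reaction table from
    :func:`reaction_enzyme_log2fc`. With ``allow_missing_enzyme`` the enzyme
    requirement is waived and such reactions are later scored with an enzyme
    term of 0.
    """
    metab_ids = set(_fc_series(metab_fc).index)
    enzyme_rids: set[str] = set() if enzyme_fc is None else set(_fc_series(enzyme_fc).index)
    out = []
    for rid, rxn in net.reactions.items():
        if not any(c in metab_ids for c, _ in rxn.substrates):
            continue
        if not any(c in metab_ids for c, _ in rxn.products):
            continue
        if not allow_missing_enzyme and rid not in enzyme_rids:
            continue
        out.append(rid)
    return out


def reaction_log2fc(
    rxn: Reaction,
    metab_fc: pd.DataFrame | pd.Series,
    enzyme_fc: pd.DataFrame | pd.Series | None,
    allow_missing_enzyme: bool = False,
) -> ReactionPotentialResult:
    """Estimate log2FC of the reaction's rate potential.

    ``metab_fc`` is keyed by compound id, ``enzyme_fc`` by reaction id (see
    :func:`reaction_enzyme_log2fc`); unmeasured substrate/product slots
    contribute nothing and are excluded from the bootstrap topology.
    """
    metab = _fc_series(metab_fc)
    breakdown: list[tuple[str, float]] = []

    enz = _fc_series(enzyme_fc) if enzyme_fc is not None else pd.Series(dtype=float)
    if rxn.id in enz.index:
        enzyme_term = float(enz[rxn.id])
        n_enz = 1
        if enzyme_fc is not None and not isinstance(enzyme_fc, pd.Series):
            n_enz = int(enzyme_fc.loc[rxn.id].get("n_enzymes_measured", 1))
    elif allow_missing_enzyme:
        enzyme_term, n_enz = 0.0, 0
    else:
        raise ValueError(f"reaction {rxn.id!r} has no measured enzyme")
    breakdown.append(("enzyme", enzyme_term))

    sub_m: list[int] = []
    for cid, m in rxn.substrates:
        if cid in metab.index:
            breakdown.append((f"substrate:{cid}", float(metab[cid]) * m))
            sub_m.append(m)
    prod_m: list[int] = []
    for cid, m in rxn.products:
        if cid in metab.index:
            breakdown.append((f"product:{cid}", -float(metab[cid]) * m))
            prod_m.append(m)
    if not sub_m or not prod_m:
        raise ValueError(f"reaction {rxn.id!r} is not testable (unmeasured side)")

    total = float(sum(v for _, v in breakdown))
    return ReactionPotentialResult(
        reaction_id=rxn.id,
        log2fc_r=total,
        breakdown=tuple(breakdown),
        n_substrates_measured=len(sub_m),
        n_products_measured=len(prod_m),
        n_enzymes_measured=n_enz,
        substrate_exponents=tuple(sub_m),
        product_exponents=tuple(prod_m),
    )


def compute_reaction_potentials(
    net: ReactionNetwork,
    metab_fc: pd.DataFrame | pd.Series,
    enzyme_fc: pd.DataFrame | pd.Series | None,
    allow_missing_enzyme: bool = False,
) -> list[ReactionPotentialResult]:
    """Score every testable reaction in the network."""
    testable = select_testable_reactions(net, metab_fc, enzyme_fc, allow_missing_enzyme)
    return [
        reaction_log2fc(net.reactions[rid], metab_fc, enzyme_fc, allow_missing_enzyme)
        for rid in testable
    ]


def _reaction_rng(seed: int, reaction_id: str) -> np.random.Generator:
    # independent, order-invariant stream per reaction
    return np.random.default_rng([seed, zlib.crc32(reaction_id.encode())])


def bootstrap_ranking_scores(
    results: list[ReactionPotentialResult],
    metab_fc: pd.DataFrame | pd.Series,
    enzyme_fc: pd.DataFrame | pd.Series | None,
    n_boot: int = 500,
    seed: int = 0,
) -> list[ReactionPotentialResult]:
    """Attach bootstrap ranking scores, preserving each reaction's topology.

    For each reaction ``n_boot`` null values are built by redrawing every
    measured metabolite slot from the pool of all measured metabolite
    fold-changes and the enzyme slot from the pool of all per-reaction enzyme
    fold-changes, keeping the slot counts and m exponents. The score is
    ``(1 + #{|null| >= |observed|}) / (n_boot + 1)``; results are
    reproducible for a given seed and independent of reaction order.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    metab_pool = _fc_series(metab_fc).to_numpy(dtype=float)
    if metab_pool.size == 0:
        raise ValueError("empty metabolite fold-change pool")
    enz_pool = (
        _fc_series(enzyme_fc).to_numpy(dtype=float) if enzyme_fc is not None else np.array([])
    )

    out = []
    for res in results:
        rng = _reaction_rng(seed, res.reaction_id)
        n_slots = len(res.substrate_exponents) + len(res.product_exponents)
        draws = metab_pool[rng.integers(0, metab_pool.size, size=(n_boot, n_slots))]
        weights = np.concatenate(
            [np.asarray(res.substrate_exponents), -np.asarray(res.product_exponents)]
        ).astype(float)
        null = draws @ weights
        if res.n_enzymes_measured > 0 and enz_pool.size > 0:
            null = null + enz_pool[rng.integers(0, enz_pool.size, size=n_boot)]
        exceed = int((np.abs(null) >= abs(res.log2fc_r)).sum())
        score = (1.0 + exceed) / (n_boot + 1.0)
        out.append(replace(res, ranking_score=score))
    return out


def call_significant_reactions(
    results: list[ReactionPotentialResult],
    score_cutoff: float = 0.05,
    fc_cutoff: float = 0.5,
) -> list[ReactionPotentialResult]:
    """Flag reactions with ranking score < score_cutoff and |log2FC_r| > fc_cutoff."""
    return [
        replace(
            r,
            significant=(r.ranking_score < score_cutoff) and (abs(r.log2fc_r) > fc_cutoff),
        )
        for r in results
    ]


def results_to_frame(results: list[ReactionPotentialResult]) -> pd.DataFrame:
    """Tabular view of the results (one row per reaction)."""
    frame = pd.DataFrame(
        [
            {
                "reaction_id": r.reaction_id,
                "log2FC_r": r.log2fc_r,
                "ranking_score": r.ranking_score,
                "n_substrates_measured": r.n_substrates_measured,
                "n_products_measured": r.n_products_measured,
                "n_enzymes_measured": r.n_enzymes_measured,
                "significant": r.significant,
                "direction": r.direction,
            }
            for r in results
        ],
        columns=[
            "reaction_id",
            "log2FC_r",
            "ranking_score",
            "n_substrates_measured",
            "n_products_measured",
            "n_enzymes_measured",
            "significant",
            "direction",
        ],
    )
    return frame.set_index("reaction_id")
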