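"""Synthetic networks, simulated two-group datasets, and the ROC benchmark.

The generative model mimics untargeted metabolomics / RNA-seq style data:
per feature a mean intensity mu is drawn from a gamma distribution, and
log2-scale replicates are normal around log2(mu + 1) with a standard
deviation that decays with the mean, sigma(mu) = a * exp(-b * log2(mu + 1))
+ c — bright features are measured more precisely than dim ones. A fixed
fraction of reactions (default 10%, half up and half down) is planted as
truly changed: their substrates and enzyme genes receive +effect and their
products -effect on the log2 mean (signs mirrored for down-reactions), so a
changed reaction's rate potential moves coherently. A metabolite or enzyme
pulled in opposite directions by two changed reactions is reset to unchanged
and labelled null. Matrices are emitted on the linear scale so the whole
preprocessing path is exercised.

The benchmark scores each testable reaction by |log2FC_r| against the truth
labels with a ROC curve, with and without the enzyme term, reproducing the
simulation study's AUC grid over metabolite and enzyme effect sizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

from .de import moderated_t_test
from .network import Compound, EnzymeDefinition, Pathway, Reaction, ReactionNetwork
from .potential import (
    compute_reaction_potentials,
    reaction_enzyme_log2fc,
    results_to_frame,
)
from .preprocess import (
    AbundanceMatrix,
    aggregate_enzyme_activity,
    filter_missing,
    impute_min,
    preprocess_pipeline,
    quantile_normalize,
)

__all__ = [
    "GammaParams",
    "DecayParams",
    "SimulationScenario",
    "SimulatedDataset",
    "synthesize_network",
    "simulate_dataset",
    "score_simulated_dataset",
    "evaluate_roc",
    "run_benchmark_grid",
]


@dataclass(frozen=True)
class GammaParams:
    """Shape/scale of the gamma distribution of per-feature mean intensities."""

    shape: float
    scale: float


@dataclass(frozen=True)
class DecayParams:
    """sigma(mu) = a * exp(-b * log2(mu + 1)) + c on the log2 scale."""

    a: float = 0.8
    b: float = 0.25
    c: float = 0.38

    def sigma(self, log2_mean: np.ndarray) -> np.ndarray:
        return self.a * np.exp(-self.b * log2_mean) + self.c


# Defaults emulate the intensity scales and replicate precision of untargeted
# metabolomics versus RNA-seq: metabolite intensities are noisy (log2-scale
# replicate SD ~0.4-0.5 for bright features, CV roughly 30-40%) while
# transcript abundances are measured far more precisely (SD ~0.04-0.1).
METABOLITE_GAMMA = GammaParams(shape=1.2, scale=3000.0)
GENE_GAMMA = GammaParams(shape=0.8, scale=800.0)
METABOLITE_DECAY = DecayParams(a=0.8, b=0.25, c=0.38)
GENE_DECAY = DecayParams(a=0.15, b=0.25, c=0.02)


@dataclass(frozen=True)
class SimulationScenario:
    """Parameters of one simulated two-group experiment."""

    network: ReactionNetwork
    seed: int
    n_replicates: int = 6
    changed_fraction: float = 0.10
    effect: float = 0.3
    enzyme_effect: float | None = None
    concordant_products: bool = False
    metabolite_gamma: GammaParams = METABOLITE_GAMMA
    gene_gamma: GammaParams = GENE_GAMMA
    decay: DecayParams = METABOLITE_DECAY
    gene_decay: DecayParams = GENE_DECAY

    def __post_init__(self) -> None:
        if not 0 < self.changed_fraction < 1:
            raise ValueError("changed_fraction must be in (0, 1)")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")


@dataclass
class SimulatedDataset:
    """Matrices plus truth labels of a simulated experiment.

    ``planted`` records the reaction directions selected for change before
    any effect or conflict handling (useful as the label set for null
    calibration at effect 0); ``truth`` is the effective label after conflict
    resolution and zero-effect collapse. ``metabolite_truth`` /
    ``enzyme_truth`` carry the per-feature effective directions (conflicted
    features are null).
    """

    metabolites: AbundanceMatrix
    genes: AbundanceMatrix
    truth: dict[str, str]
    planted: dict[str, str]
    metabolite_truth: dict[str, str]
    enzyme_truth: dict[str, str]


def synthesize_network(
    n_compounds: int = 2000,
    n_reactions: int = 3000,
    n_enzymes: int = 1500,
    seed: int = 0,
    max_side: int = 3,
    p_m2: float = 0.10,
    reactions_per_pathway: int = 25,
) -> ReactionNetwork:
    """Random bipartite compound-reaction network with enzyme structure.

    Each reaction draws 1-3 substrates and 1-3 products (distinct compounds;
    m = 2 with probability ``p_m2``) and one enzyme; enzymes have 1-3
    isoenzymes of 1-2 subunit genes each (genes are private to an enzyme).
    Pathways are formed by chunking the reaction list; each pathway's member
    compounds are those of its reactions.
    """
    if n_compounds < 2 * max_side:
        raise ValueError("not enough compounds to populate reactions")
    if min(n_compounds, n_reactions, n_enzymes) < 1:
        raise ValueError("all sizes must be positive")
    rng = np.random.default_rng(seed)
    compounds = [f"C{i:05d}" for i in range(n_compounds)]
    net = ReactionNetwork(compounds={c: Compound(c) for c in compounds})

    gene_counter = 0
    for e in range(n_enzymes):
        eid = f"E{e:05d}"
        isoenzymes = []
        for _ in range(rng.integers(1, 4)):
            n_sub = int(rng.integers(1, 3))
            genes = tuple(f"G{gene_counter + k:06d}" for k in range(n_sub))
            gene_counter += n_sub
            isoenzymes.append(genes)
        net.enzymes[eid] = EnzymeDefinition(eid, tuple(isoenzymes))

    enzyme_ids = list(net.enzymes)
    for r in range(n_reactions):
        rid = f"R{r:05d}"
        n_sub = int(rng.integers(1, max_side + 1))
        n_prod = int(rng.integers(1, max_side + 1))
        chosen = rng.choice(n_compounds, size=n_sub + n_prod, replace=False)
        ms = np.where(rng.random(n_sub + n_prod) < p_m2, 2, 1)
        subs = tuple((compounds[c], int(m)) for c, m in zip(chosen[:n_sub], ms[:n_sub]))
        prods = tuple((compounds[c], int(m)) for c, m in zip(chosen[n_sub:], ms[n_sub:]))
        enzyme = enzyme_ids[int(rng.integers(0, n_enzymes))]
        net.reactions[rid] = Reaction(rid, subs, prods, (enzyme,), True)

    rids = list(net.reactions)
    for p, start in enumerate(range(0, n_reactions, reactions_per_pathway)):
        members = rids[start : start + reactions_per_pathway]
        cpds = {c for rid in members for c in net.reactions[rid].compound_ids}
        pid = f"P{p:04d}"
        net.pathways[pid] = Pathway(pid, f"synthetic pathway {p}", frozenset(cpds), frozenset(members))
    return net


def _resolve_directions(
    assignments: dict[str, set[int]]
) -> tuple[dict[str, int], dict[str, str]]:
    """Collapse per-feature sign sets; conflicting features become unchanged."""
    effects: dict[str, int] = {}
    labels: dict[str, str] = {}
    for fid, signs in assignments.items():
        if len(signs) == 1:
            s = signs.pop()
            effects[fid] = s
            labels[fid] = "up" if s > 0 else "down"
        else:
            effects[fid] = 0
            labels[fid] = "null"
    return effects, labels


def _simulate_matrix(
    rng: np.random.Generator,
    feature_ids: list[str],
    gamma: GammaParams,
    decay: DecayParams,
    delta: np.ndarray,
    n_replicates: int,
    sample_ids: list[str],
    groups: dict[str, str],
) -> AbundanceMatrix:
    n = len(feature_ids)
    mu = rng.gamma(gamma.shape, gamma.scale, size=n)
    base = np.log2(mu + 1.0)
    sigma = decay.sigma(base)
    ref = rng.normal(base[:, None], sigma[:, None], size=(n, n_replicates))
    test = rng.normal((base + delta)[:, None], sigma[:, None], size=(n, n_replicates))
    log2_values = np.concatenate([ref, test], axis=1)
    linear = np.maximum(np.exp2(log2_values) - 1.0, 0.0)
    data = pd.DataFrame(linear, index=feature_ids, columns=sample_ids)
    return AbundanceMatrix(data=data, groups=groups, state="raw")


def simulate_dataset(scn: SimulationScenario) -> SimulatedDataset:
    """Draw one simulated experiment from the scenario (bit-reproducible)."""
    rng = np.random.default_rng(scn.seed)
    net = scn.network
    rids = list(net.reactions)
    n_changed = int(round(scn.changed_fraction * len(rids)))
    n_up = n_changed // 2 + n_changed % 2
    chosen = rng.choice(len(rids), size=n_changed, replace=False)
    planted = {rid: "null" for rid in rids}
    for pos, idx in enumerate(chosen):
        planted[rids[idx]] = "up" if pos < n_up else "down"

    # per-feature sign sets implied by the planted reaction directions
    metab_signs: dict[str, set[int]] = {}
    enzyme_signs: dict[str, set[int]] = {}
    for rid, direction in planted.items():
        if direction == "null":
            continue
        sign = 1 if direction == "up" else -1
        rxn = net.reactions[rid]
        prod_sign = sign if scn.concordant_products else -sign
        for cid, _m in rxn.substrates:
            metab_signs.setdefault(cid, set()).add(sign)
        for cid, _m in rxn.products:
            metab_signs.setdefault(cid, set()).add(prod_sign)
        for eid in rxn.enzymes:
            enzyme_signs.setdefault(eid, set()).add(sign)

    metab_effects, metab_labels = _resolve_directions(metab_signs)
    enzyme_effects, enzyme_labels = _resolve_directions(enzyme_signs)
    if scn.effect == 0:
        metab_labels = {k: "null" for k in metab_labels}
    if scn.enzyme_effect in (None, 0):
        enzyme_labels = {k: "null" for k in enzyme_labels}

    # effective reaction truth: a planted reaction whose every component was
    # nullified carries no signal, but labels follow the planted directions
    truth = dict(planted)
    if scn.effect == 0 and scn.enzyme_effect in (None, 0):
        truth = {rid: "null" for rid in truth}

    compound_ids = list(net.compounds)
    delta_m = np.array([scn.effect * metab_effects.get(c, 0) for c in compound_ids])

    gene_ids: list[str] = []
    gene_delta: list[float] = []
    enz_eff = 0.0 if scn.enzyme_effect is None else scn.enzyme_effect
    for eid, enz in net.enzymes.items():
        for gid in enz.gene_ids:
            gene_ids.append(gid)
            gene_delta.append(enz_eff * enzyme_effects.get(eid, 0))

    n_rep = scn.n_replicates
    sample_ids = [f"ref_{i + 1}" for i in range(n_rep)] + [f"test_{i + 1}" for i in range(n_rep)]
    groups = {s: ("reference" if s.startswith("ref_") else "test") for s in sample_ids}

    metabolites = _simulate_matrix(
        rng, compound_ids, scn.metabolite_gamma, scn.decay, delta_m, n_rep, sample_ids, groups
    )
    genes = _simulate_matrix(
        rng, gene_ids, scn.gene_gamma, scn.gene_decay, np.array(gene_delta), n_rep, sample_ids, groups
    )
    metab_truth = {c: metab_labels.get(c, "null") for c in compound_ids}
    enz_truth = {e: enzyme_labels.get(e, "null") for e in net.enzymes}
    return SimulatedDataset(metabolites, genes, truth, planted, metab_truth, enz_truth)


def score_simulated_dataset(
    scn: SimulationScenario,
    dataset: SimulatedDataset | None = None,
    quantile: bool = True,
) -> pd.DataFrame:
    """Run preprocessing + rate-potential estimation on a simulated dataset.

    Returns the per-reaction table with both scorers: ``log2FC_r``
    (enzyme-integrated) and ``log2FC_r_no_enzyme`` (enzyme term forced to 0).
    Bootstrap ranking is intentionally skipped here — the ROC benchmark
    thresholds |log2FC_r| directly.
    """
    ds = dataset or simulate_dataset(scn)
    net = scn.network
    metab = preprocess_pipeline(ds.metabolites, quantile=quantile)
    metab_fc = moderated_t_test(metab)

    # enzyme activities aggregated on the linear scale, then per-reaction FC
    g = impute_min(filter_missing(ds.genes))
    if quantile:
        g = quantile_normalize(g)
    activity = aggregate_enzyme_activity(g, net.enzymes)
    enzyme_fc = reaction_enzyme_log2fc(net, activity)

    integrated = compute_reaction_potentials(net, metab_fc, enzyme_fc)
    no_enzyme = compute_reaction_potentials(net, metab_fc, None, allow_missing_enzyme=True)

    frame = results_to_frame(integrated)[
        ["log2FC_r", "n_substrates_measured", "n_products_measured"]
    ]
    no_enz = results_to_frame(no_enzyme)["log2FC_r"].rename("log2FC_r_no_enzyme")
    out = frame.join(no_enz, how="inner")
    out["truth"] = [ds.truth[rid] for rid in out.index]
    out["planted"] = [ds.planted[rid] for rid in out.index]
    return out


def evaluate_roc(
    truth: dict[str, str] | pd.Series,
    scores: pd.Series,
) -> tuple[float, pd.DataFrame]:
    """AUC (trapezoid rule) and ROC points for |score| against truth labels.

    Positives are reactions labelled up or down; ``scores`` is restricted to
    the reactions present in its index (i.e. the testable ones).
    """
    labels = pd.Series(truth) if isinstance(truth, dict) else truth
    labels = labels.loc[scores.index]
    y = (labels != "null").astype(int).to_numpy()
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("ROC needs both positive and negative reactions")
    s = scores.abs().to_numpy()
    auc = float(roc_auc_score(y, s))
    fpr, tpr, thr = roc_curve(y, s)
    return auc, pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def _spawn_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def run_benchmark_grid(
    effects: Iterable[float],
    enzyme_effects: Iterable[float | None],
    n_runs: int = 20,
    seed: int = 0,
    network: ReactionNetwork | None = None,
    network_kwargs: dict | None = None,
    n_replicates: int = 6,
    changed_fraction: float = 0.10,
) -> pd.DataFrame:
    """Mean AUC (and SD) per (metabolite effect, enzyme effect) grid cell.

    ``enzyme_effects`` entries of ``None`` simulate absent enzyme data and
    report the no-enzyme scorer; numeric entries plant the enzyme effect and
    report the integrated scorer. One network is shared by all cells; the
    per-run dataset seeds are spawned from ``seed``.
    """
    effects = list(effects)
    enzyme_effects = list(enzyme_effects)
    if not effects or not enzyme_effects:
        raise ValueError("empty benchmark grid")
    net = network or synthesize_network(seed=seed, **(network_kwargs or {}))
    run_seeds = _spawn_seeds(seed, n_runs)
    rows = []
    for eff in effects:
        for enz_eff in enzyme_effects:
            aucs = []
            for run_seed in run_seeds:
                scn = SimulationScenario(
                    network=net,
                    seed=run_seed,
                    n_replicates=n_replicates,
                    changed_fraction=changed_fraction,
                    effect=eff,
                    enzyme_effect=enz_eff,
                )
                table = score_simulated_dataset(scn)
                col = "log2FC_r_no_enzyme" if enz_eff is None else "log2FC_r"
                labels = "planted" if eff == 0 and enz_eff in (None, 0) else "truth"
                auc, _ = evaluate_roc(table[labels], table[col])
                aucs.append(auc)
            rows.append(
                {
                    "metabolite_effect": eff,
                    "enzyme_effect": np.nan if enz_eff is None else enz_eff,
                    "scorer": "no_enzyme" if enz_eff is None else "integrated",
                    "mean_auc": float(np.mean(aucs)),
                    "sd_auc": float(np.std(aucs, ddof=1)) if len(aucs) > 1 else 0.0,
                    "n_runs": len(aucs),
                }
            )
    return pd.DataFrame(rows)
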