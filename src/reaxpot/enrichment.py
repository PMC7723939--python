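"""Pathway over-representation analysis (hypergeometric upper tail + BH FDR)."""

from __future__ import annotations

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .network import Pathway

__all__ = ["ora"]

_COLUMNS = ["pathway_id", "name", "k", "K", "n", "N", "ratio", "p", "fdr"]


def ora(
    significant: set[str] | list[str],
    background: set[str] | list[str],
    pathways: dict[str, Pathway] | dict[str, tuple[str, set[str]]],
    member_kind: str = "compound",
    min_size: int = 3,
    max_size: int | None = None,
) -> pd.DataFrame:
    """Hypergeometric over-representation of significant ids in each pathway.

    Each pathway's member set is intersected with the measured ``background``
    before testing; pathways with fewer than ``min_size`` (default 3) members
    in the background are skipped. ``member_kind`` picks compound or reaction
    membership when ``pathways`` holds :class:`~reaxpot.network.Pathway`
    objects. The p-value is P(X >= k) for k of n draws landing in a pathway
    of size K within a universe of size N; BH adjustment runs across the
    tested pathways and rows are sorted by p.
    """
    background = set(background)
    significant = set(significant)
    if not background:
        raise ValueError("empty background")
    stray = significant - background
    if stray:
        raise ValueError(f"significant ids outside the background: {sorted(stray)[:5]}")
    if member_kind not in ("compound", "reaction"):
        raise ValueError("member_kind must be 'compound' or 'reaction'")

    n_total = len(significant)
    n_bg = len(background)
    rows = []
    for pid in sorted(pathways):
        pw = pathways[pid]
        if isinstance(pw, Pathway):
            name = pw.name
            members = pw.compounds if member_kind == "compound" else pw.reactions
        else:
            name, members = pw[0], set(pw[1])
        in_bg = set(members) & background
        big_k = len(in_bg)
        if big_k < min_size or (max_size is not None and big_k > max_size):
            continue
        k = len(in_bg & significant)
        p = float(hypergeom.sf(k - 1, n_bg, big_k, n_total))
        ratio = (k / n_total) / (big_k / n_bg) if n_total > 0 else float("nan")
        rows.append(
            {
                "pathway_id": pid,
                "name": name,
                "k": k,
                "K": big_k,
                "n": n_total,
                "N": n_bg,
                "ratio": ratio,
                "p": min(p, 1.0),
            }
        )
    if not rows:
        return pd.DataFrame(columns=_COLUMNS).set_index("pathway_id")
    out = pd.DataFrame(rows)
    out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    return out.sort_values(["p", "pathway_id"], kind="mergesort").set_index("pathway_id")
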