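"""Bipartite compound-reaction graphs with significance annotations.

Two views mirror how the results are explored: the *pathway view* shows one
pathway's reactions with every measured metabolite regardless of
significance; the *global view* starts from the significant metabolites and
reactions and expands one hop to their associated reactions and measured
metabolites. Graphs are exported as GraphML, Cytoscape JSON, or a
self-contained interactive HTML page.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import networkx as nx
import pandas as pd

from .network import ReactionNetwork
from .potential import ReactionPotentialResult

__all__ = ["pathway_view", "global_view", "network_to_graph", "export_graph"]


def _node_attrs(kind: str, log2fc: float | None, significant: bool, measured: bool,
                score: float | None = None) -> dict:
    attrs = {"kind": kind, "significant": bool(significant), "measured": bool(measured)}
    if log2fc is not None and not (isinstance(log2fc, float) and math.isnan(log2fc)):
        attrs["log2FC"] = float(log2fc)
    if score is not None and not (isinstance(score, float) and math.isnan(score)):
        attrs["score"] = float(score)
    return attrs


def _annotate(
    g: nx.Graph,
    net: ReactionNetwork,
    compound_ids: set[str],
    reaction_ids: set[str],
    metab_fc: pd.DataFrame | None,
    rxn_results: dict[str, ReactionPotentialResult],
) -> nx.Graph:
    metab = metab_fc if metab_fc is not None else pd.DataFrame()
    for cid in compound_ids:
        measured = cid in metab.index
        row = metab.loc[cid] if measured else None
        g.add_node(
            cid,
            **_node_attrs(
                "compound",
                float(row["log2FC"]) if measured else None,
                bool(row["significant"]) if measured and "significant" in metab.columns else False,
                measured,
            ),
        )
    for rid in reaction_ids:
        res = rxn_results.get(rid)
        g.add_node(
            rid,
            **_node_attrs(
                "reaction",
                res.log2fc_r if res else None,
                res.significant if res else False,
                res is not None,
                res.ranking_score if res else None,
            ),
        )
    for rid in reaction_ids:
        rxn = net.reactions[rid]
        for cid, _m in rxn.substrates:
            if cid in compound_ids:
                g.add_edge(cid, rid, role="substrate")
        for cid, _m in rxn.products:
            if cid in compound_ids:
                g.add_edge(rid, cid, role="product")
    for node in g.nodes:
        g.nodes[node]["degree"] = g.degree[node]
    return g


def network_to_graph(net: ReactionNetwork) -> nx.Graph:
    """Bare bipartite graph of the whole network (no annotations)."""
    return _annotate(
        nx.Graph(), net, set(net.compounds), set(net.reactions), None, {}
    )


def pathway_view(
    net: ReactionNetwork,
    pathway_id: str,
    metab_fc: pd.DataFrame | None = None,
    rxn_results: list[ReactionPotentialResult] | None = None,
) -> nx.Graph:
    """One pathway's reactions plus all their *measured* compounds.

    Measured metabolites appear whether or not they are significant; the
    pathway's own measured member compounds are always included.
    """
    if pathway_id not in net.pathways:
        raise KeyError(f"unknown pathway {pathway_id!r}")
    pw = net.pathways[pathway_id]
    results = {r.reaction_id: r for r in rxn_results or []}
    measured = set(metab_fc.index) if metab_fc is not None else set()
    rids = set(pw.reactions)
    cids = set()
    for rid in rids:
        cids |= {c for c in net.reactions[rid].compound_ids if c in measured}
    cids |= pw.compounds & measured
    g = _annotate(nx.Graph(), net, cids, rids, metab_fc, results)
    g.graph.update(pathway_id=pw.id, pathway_name=pw.name, view="pathway")
    return g


def global_view(
    net: ReactionNetwork,
    metab_fc: pd.DataFrame,
    rxn_results: list[ReactionPotentialResult],
    hops: int = 1,
) -> nx.Graph:
    """Significant metabolites and reactions plus a one-hop neighbourhood.

    Seed = significant metabolites and significant reactions; each hop adds
    the reactions touching included metabolites and the measured metabolites
    touching included reactions. An empty seed yields an empty graph with a
    ``warning`` graph attribute.
    """
    results = {r.reaction_id: r for r in rxn_results}
    measured = set(metab_fc.index)
    if "significant" in metab_fc.columns:
        sig_c = set(metab_fc.index[metab_fc["significant"].astype(bool)])
    else:
        sig_c = set()
    sig_r = {r.reaction_id for r in rxn_results if r.significant}
    g = nx.Graph(view="global")
    if not sig_c and not sig_r:
        g.graph["warning"] = "no significant metabolites or reactions; empty graph"
        return g
    cids, rids = set(sig_c), set(sig_r)
    for _ in range(max(hops, 0)):
        rids = rids | {
            rid
            for rid, rxn in net.reactions.items()
            if any(c in cids for c in rxn.compound_ids)
        }
        cids = cids | {
            c for rid in rids for c in net.reactions[rid].compound_ids if c in measured
        }
    g = _annotate(g, net, cids, rids, metab_fc, results)
    g.graph["view"] = "global"
    return g


_HTML_TEMPLATE = """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>reaxpot network</title>
<style>
 body {{ font-family: sans-serif; margin: 0; }}
 #info {{ position: absolute; top: 8px; left: 8px; background: #fff8; padding: 4px 8px;
         border-radius: 4px; font-size: 13px; }}
 canvas {{ display: block; }}
</style></head>
<body>
<div id="info">drag to pan &middot; hover a node for details</div>
<canvas id="net"></canvas>
<script>
const data = {payload};
const nodes = data.elements.nodes.map(n => ({{...n.data, x: Math.random()*800, y: Math.random()*600, vx: 0, vy: 0}}));
const byId = Object.fromEntries(nodes.map(n => [n.id, n]));
const edges = data.elements.edges.map(e => ({{s: byId[e.data.source], t: byId[e.data.target]}}));
const canvas = document.getElementById('net');
const ctx = canvas.getContext('2d');
function resize() {{ canvas.width = innerWidth; canvas.height = innerHeight; }}
resize(); addEventListener('resize', resize);
let ox = 0, oy = 0, dragging = false, px = 0, py = 0;
canvas.onmousedown = e => {{ dragging = true; px = e.clientX; py = e.clientY; }};
canvas.onmouseup = () => dragging = false;
let hover = null;
canvas.onmousemove = e => {{
  if (dragging) {{ ox += e.clientX - px; oy += e.clientY - py; px = e.clientX; py = e.clientY; }}
  hover = nodes.find(n => Math.hypot(n.x + ox - e.clientX, n.y + oy - e.clientY) < 8) || null;
}};
function color(n) {{
  if (n.log2FC === undefined) return '#bbb';
  const v = Math.max(-2, Math.min(2, n.log2FC)) / 2;
  return v >= 0 ? `rgba(200,30,30,${{0.25 + 0.75 * v}})` : `rgba(30,60,200,${{0.25 - 0.75 * v}})`;
}}
function step() {{
  for (const n of nodes) {{ n.vx *= 0.6; n.vy *= 0.6; }}
  for (let i = 0; i < nodes.length; i++) for (let j = i + 1; j < nodes.length; j++) {{
    const a = nodes[i], b = nodes[j];
    let dx = a.x - b.x, dy = a.y - b.y, d2 = dx * dx + dy * dy + 0.01;
    const f = 1200 / d2; a.vx += dx * f; a.vy += dy * f; b.vx -= dx * f; b.vy -= dy * f;
  }}
  for (const e of edges) {{
    const dx = e.t.x - e.s.x, dy = e.t.y - e.s.y;
    const d = Math.hypot(dx, dy), f = (d - 60) * 0.02;
    e.s.vx += dx / d * f; e.s.vy += dy / d * f; e.t.vx -= dx / d * f; e.t.vy -= dy / d * f;
  }}
  const cx = canvas.width / 2, cy = canvas.height / 2;
  for (const n of nodes) {{
    n.vx += (cx - n.x) * 0.002; n.vy += (cy - n.y) * 0.002; n.x += n.vx; n.y += n.vy;
  }}
}}
function draw() {{
  step();
  ctx.clearRect(0, 0, canvas.width, canvas.height);
  ctx.save(); ctx.translate(ox, oy);
  ctx.strokeStyle = '#ccc';
  for (const e of edges) {{
    ctx.beginPath(); ctx.moveTo(e.s.x, e.s.y); ctx.lineTo(e.t.x, e.t.y); ctx.stroke();
  }}
  for (const n of nodes) {{
    const r = 4 + 1.5 * Math.sqrt(n.degree || 1);
    ctx.beginPath();
    if (n.kind === 'reaction') ctx.rect(n.x - r, n.y - r, 2 * r, 2 * r);
    else ctx.arc(n.x, n.y, r, 0, 7);
    ctx.fillStyle = color(n); ctx.fill();
    ctx.strokeStyle = n.significant ? '#000' : '#999'; ctx.stroke();
  }}
  if (hover) {{
    ctx.fillStyle = '#000'; ctx.font = '13px sans-serif';
    const txt = hover.id + (hover.log2FC !== undefined ? ' log2FC=' + hover.log2FC.toFixed(3) : '')
      + (hover.score !== undefined ? ' score=' + hover.score.toFixed(3) : '');
    ctx.fillText(txt, hover.x + 10, hover.y - 10);
  }}
  ctx.restore();
  requestAnimationFrame(draw);
}}
draw();
</script></body></html>
"""


def export_graph(g: nx.Graph, path: str | Path, fmt: str | None = None) -> Path:
    """Write the graph as ``graphml``, ``cytoscape-json`` or ``html``.

    ``fmt`` defaults from the file suffix. GraphML and Cytoscape JSON keep
    every node/edge attribute; the HTML page embeds the Cytoscape JSON with a
    small force-directed renderer (no external resources).
    """
    path = Path(path)
    if fmt is None:
        fmt = {".graphml": "graphml", ".json": "cytoscape-json", ".html": "html"}.get(
            path.suffix.lower(), ""
        )
    if fmt == "graphml":
        nx.write_graphml(g, path)
    elif fmt == "cytoscape-json":
        path.write_text(json.dumps(nx.cytoscape_data(g), indent=1))
    elif fmt == "html":
        payload = json.dumps(nx.cytoscape_data(g))
        path.write_text(_HTML_TEMPLATE.format(payload=payload))
    else:
        raise ValueError(f"unknown graph format {fmt!r}")
    return path
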