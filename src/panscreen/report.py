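"""Static HTML report with four sections: significant genes, lineage test,
co-occurrence heatmaps, and ordinations."""

from __future__ import annotations

import base64
import io
from pathlib import Path

import numpy as np
import pandas as pd
from jinja2 import Template

_TEMPLATE = Template(
    """<!DOCTYPE html>
<html>
<head>
<meta charset="utf-8">
<title>panscreen report</title>
<style>
body { font-family: sans-serif; margin: 2em; max-width: 1100px; }
h2 { border-bottom: 1px solid #999; padding-bottom: 0.2em; }
table { border-collapse: collapse; font-size: 0.85em; }
th, td { border: 1px solid #ccc; padding: 2px 8px; }
tr.flagged { background: #ffe0e0; }
.meta { color: #666; font-size: 0.85em; }
img { max-width: 100%; }
</style>
</head>
<body>
<h1>panscreen report</h1>
<p class="meta">seed {{ seed }} &middot; alpha {{ alpha }} &middot;
flag threshold: family rank &gt; {{ flag_threshold }}</p>

<h2>1. Significant genes</h2>
<p>{{ n_significant }} of {{ n_tested }} genes significant at q &le; {{ alpha }}.</p>
{{ prevalence_table }}

<h2>2. Correlation lineage test</h2>
<p>{{ n_flagged }} gene(s) flagged as putative contaminants
(family match rank &gt; {{ flag_threshold }} or no family match).</p>
{{ lineage_table }}

<h2>3. Co-occurrence heatmaps</h2>
{% for species, img in heatmaps.items() %}
<h3>{{ species }}</h3>
{% if img %}<img src="data:image/png;base64,{{ img }}" alt="heatmap {{ species }}">{% else %}<p class="meta">figure generation disabled</p>{% endif %}
{% endfor %}
{% if not heatmaps %}<p class="meta">no species had &ge; 3 significant genes</p>{% endif %}

<h2>4. Ordinations</h2>
{% for species, methods in ordinations.items() %}
<h3>{{ species }}</h3>
{% for method, img in methods.items() %}
<h4>{{ method }}</h4>
{% if img %}<img src="data:image/png;base64,{{ img }}" alt="{{ method }} {{ species }}">{% else %}<p class="meta">figure generation disabled</p>{% endif %}
{% endfor %}
{% endfor %}
{% if not ordinations %}<p class="meta">no ordinations computed</p>{% endif %}
</body>
</html>
"""
)


def _fig_to_base64(fig) -> str:
    buf = io.BytesIO()
    fig.savefig(buf, format="png", dpi=90, bbox_inches="tight")
    import matplotlib.pyplot as plt

    plt.close(fig)
    return base64.b64encode(buf.getvalue()).decode("ascii")


def _heatmap_figure(gene_order: list[str], similarity: np.ndarray):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(similarity, cmap="viridis", vmin=0, vmax=1)
    ax.set_xticks(range(len(gene_order)))
    ax.set_yticks(range(len(gene_order)))
    ax.set_xticklabels(gene_order, rotation=90, fontsize=5)
    ax.set_yticklabels(gene_order, fontsize=5)
    fig.colorbar(im, ax=ax, label="Jaccard similarity")
    return fig


def _ordination_figure(frame: pd.DataFrame, method: str):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(frame["axis1"], frame["axis2"], s=12)
    for _, row in frame.iterrows():
        ax.annotate(
            str(row["gene_id"]), (row["axis1"], row["axis2"]), fontsize=4
        )
    ax.set_xlabel("axis 1")
    ax.set_ylabel("axis 2")
    title = method
    if "stress" in frame.columns:
        title += f" (stress {frame['stress'].iloc[0]:.3f})"
    ax.set_title(title)
    return fig


def render_report(
    out_dir: Path,
    prevalence: pd.DataFrame,
    lineage: pd.DataFrame,
    heatmaps: dict[str, tuple[list[str], np.ndarray]],
    ordinations: dict[str, dict[str, pd.DataFrame]],
    config,
    make_figures: bool = True,
) -> Path:
    heatmap_imgs = {}
    for species, (order, sim) in heatmaps.items():
        heatmap_imgs[species] = (
            _fig_to_base64(_heatmap_figure(order, sim)) if make_figures else None
        )
    ordination_imgs: dict[str, dict[str, str | None]] = {}
    for species, methods in ordinations.items():
        ordination_imgs[species] = {
            method: (
                _fig_to_base64(_ordination_figure(frame, method))
                if make_figures
                else None
            )
            for method, frame in methods.items()
        }
    sig = prevalence[prevalence["significant"]]
    lineage_html = lineage.to_html(index=False, na_rep="", border=0)
    html = _TEMPLATE.render(
        seed=config.seed,
        alpha=config.alpha,
        flag_threshold=config.flag_rank_threshold,
        n_tested=len(prevalence),
        n_significant=len(sig),
        n_flagged=int(lineage["flagged"].sum()) if len(lineage) else 0,
        prevalence_table=sig.to_html(index=False, border=0),
        lineage_table=lineage_html,
        heatmaps=heatmap_imgs,
        ordinations=ordination_imgs,
    )
    path = Path(out_dir) / "report.html"
    path.write_text(html, encoding="utf-8")
    return path
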