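"""HTML rendering of per-fly QC reports and dataset evaluation sheets.

The JSON report dicts produced by :mod:`torquelearn.qc` and
:mod:`torquelearn.stats` are the canonical machine-readable outputs;
these renderers wrap them in small self-contained HTML documents with
an inline SVG plot of the raw torque envelope.
"""

from __future__ import annotations

import html
import json
from pathlib import Path

__all__ = ["render_qc_html", "render_dataset_html", "write_reports"]

_STYLE = """
body { font-family: sans-serif; margin: 2em; color: #222; }
table { border-collapse: collapse; margin: 1em 0; }
th, td { border: 1px solid #999; padding: 0.25em 0.6em; text-align: right; }
th { background: #eee; }
.pass { color: #060; } .fail { color: #a00; font-weight: bold; }
"""


def _svg_envelope(env: dict, width: int = 900, height: int = 180) -> str:
    t = env.get("t_s", [])
    lo = env.get("torque_min", [])
    hi = env.get("torque_max", [])
    if not t:
        return "<p>(no trace)</p>"
    t0, t1 = t[0], t[-1]
    ymin, ymax = min(lo), max(hi)
    if ymax == ymin:
        ymax = ymin + 1.0

    def sx(v):
        return (v - t0) / (t1 - t0 + 1e-12) * (width - 20) + 10

    def sy(v):
        return height - 10 - (v - ymin) / (ymax - ymin) * (height - 20)

    pts = [f"{sx(x):.1f},{sy(y):.1f}" for x, y in zip(t, hi)]
    pts += [f"{sx(x):.1f},{sy(y):.1f}" for x, y in zip(reversed(t), reversed(lo))]
    zero = sy(0.0) if ymin < 0 < ymax else None
    zero_line = (
        f'<line x1="10" y1="{zero:.1f}" x2="{width - 10}" y2="{zero:.1f}" '
        'stroke="#c00" stroke-dasharray="4"/>'
        if zero is not None
        else ""
    )
    return (
        f'<svg width="{width}" height="{height}" '
        f'xmlns="http://www.w3.org/2000/svg">'
        f'<polygon points="{" ".join(pts)}" fill="#69c" stroke="none"/>'
        f"{zero_line}</svg>"
    )


def render_qc_html(report: dict) -> str:
    rows = "".join(
        f'<tr><td>{html.escape(c["rule"])}</td>'
        f'<td class="{"pass" if c["pass"] else "fail"}">'
        f'{"pass" if c["pass"] else "FAIL"}</td>'
        f'<td style="text-align:left">{html.escape(c["detail"])}</td></tr>'
        for c in report["checks"]
    )
    pi_rows = "".join(
        f'<tr><td>{r["period"]}</td><td>{r["ta_s"]}</td><td>{r["tb_s"]}</td>'
        f'<td>{"-" if r["pi"] is None else r["pi"]}</td></tr>'
        for r in report["performance_indices"]
    )
    om_rows = ""
    for phase in ("before", "after"):
        for f in report["om_fits"].get(phase, []):
            om_rows += (
                f'<tr><td>{phase}</td><td>{f["direction"]}</td>'
                f'<td>{f["model"]}</td><td>{f["magnitude"]}</td>'
                f'<td>{f["residual_sd"]}</td></tr>'
            )
    verdict = "INCLUDED" if report["included"] else "EXCLUDED"
    return f"""<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>QC {html.escape(report["fly_id"])}</title>
<style>{_STYLE}</style></head><body>
<h1>Quality control: {html.escape(report["fly_id"])}</h1>
<p>Setup: {html.escape(report["setup"])}; punished domain:
{html.escape(report["punished_domain"])}; decision:
<span class="{"pass" if report["included"] else "fail"}">{verdict}</span></p>
<h2>Raw torque trace (min/max envelope)</h2>
{_svg_envelope(report["trace_envelope"])}
<h2>Exclusion rules</h2>
<table><tr><th>rule</th><th>outcome</th><th>detail</th></tr>{rows}</table>
<h2>Performance indices</h2>
<table><tr><th>period</th><th>ta (s)</th><th>tb (s)</th><th>PI</th></tr>{pi_rows}</table>
<h2>Optomotor fits</h2>
<table><tr><th>phase</th><th>direction</th><th>model</th><th>magnitude</th>
<th>residual sd</th></tr>{om_rows or "<tr><td colspan=5>none</td></tr>"}</table>
</body></html>"""


def render_dataset_html(report: dict) -> str:
    group_rows = ""
    for name, g in report["groups"].items():
        group_rows += (
            f'<tr><td style="text-align:left">{html.escape(name)}</td>'
            f'<td>{g["n_included"]}</td><td>{g["median_pi"]:.3f}</td>'
            f'<td>{g["p_value"]:.4g}</td><td>{g["bayes_factor"]:.4g}</td>'
            f'<td>{html.escape(g["classification"])}</td></tr>'
        )
    fly_rows = ""
    for name, g in report["groups"].items():
        for r in g["table"]:
            status = "included" if r["included"] else (
                "excluded: " + ", ".join(r["excluded_by"])
            )
            fly_rows += (
                f'<tr><td style="text-align:left">{html.escape(name)}</td>'
                f'<td style="text-align:left">{html.escape(r["fly_id"])}</td>'
                f'<td>{html.escape(r["punished_domain"])}</td>'
                f'<td style="text-align:left">{html.escape(status)}</td>'
                f'<td>{"-" if r["learning_pi"] is None else r["learning_pi"]}</td></tr>'
            )
    comp_rows = "".join(
        f'<tr><td style="text-align:left">{html.escape(" vs ".join(c["groups"]))}</td>'
        f'<td>{c["p_value"]:.4g}</td><td>{c["bayes_factor"]:.4g}</td></tr>'
        for c in report["comparisons"]
    )
    om = report.get("optomotor")
    om_block = ""
    if om:
        om_block = f"<h2>Optomotor asymmetry</h2><pre>{html.escape(json.dumps(om, indent=2))}</pre>"
    return f"""<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>Dataset evaluation</title>
<style>{_STYLE}</style></head><body>
<h1>Dataset evaluation</h1>
<p>alpha = {report["alpha"]}, Bayes-factor thresholds:
&gt; {report["bf_upper"]} (learning), &lt; {report["bf_lower"]} (no learning)</p>
<h2>Group verdicts</h2>
<table><tr><th>group</th><th>n</th><th>median PI</th><th>p (Wilcoxon)</th>
<th>BF10</th><th>verdict</th></tr>{group_rows}</table>
<h2>Flies</h2>
<table><tr><th>group</th><th>fly</th><th>punished</th><th>status</th>
<th>learning PI</th></tr>{fly_rows}</table>
<h2>Group comparisons</h2>
<table><tr><th>pair</th><th>p (Mann-Whitney)</th><th>BF10</th></tr>
{comp_rows or "<tr><td colspan=3>none</td></tr>"}</table>
{om_block}
</body></html>"""


def write_reports(report: dict, out_dir: str | Path) -> None:
    """Write dataset JSON + HTML and one JSON + HTML sheet per fly."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "dataset_evaluation.json", "w") as fh:
        json.dump(report, fh, indent=1)
    (out / "dataset_evaluation.html").write_text(render_dataset_html(report))
    for fly in report.get("flies", []):
        stem = out / f"qc_{fly['fly_id']}"
        with open(f"{stem}.json", "w") as fh:
            json.dump(fly, fh, indent=1)
        Path(f"{stem}.html").write_text(render_qc_html(fly))
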