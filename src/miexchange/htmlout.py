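"""Write-only HTML rendering of interaction records for quick human
consumption in a browser.

One self-contained document: inline style, no external assets, a fixed
layout — one section per interaction with a summary block and a
participants table (id, roles, organism, features). Output is deterministic
given input order and well-formed (XML-parseable) HTML5.
"""

from __future__ import annotations

from html import escape
from typing import Iterable, Optional

from .model import CvTerm, Interaction, Organism, Participant

_STYLE = """
body { font-family: sans-serif; margin: 2em; color: #222; }
h1 { font-size: 1.4em; } h2 { font-size: 1.1em; margin-top: 1.5em; }
table { border-collapse: collapse; margin: 0.5em 0; }
th, td { border: 1px solid #999; padding: 0.3em 0.6em; font-size: 0.9em; }
th { background: #eee; text-align: left; }
dl.summary dt { font-weight: bold; float: left; clear: left; width: 11em; }
dl.summary dd { margin-left: 12em; }
p.notice { color: #666; font-style: italic; }
""".strip()


def _cv_text(term: Optional[CvTerm]) -> str:
    if term is None:
        return "-"
    if term.mi_identifier:
        return f"{term.short_name} [{term.mi_identifier}]"
    return term.short_name


def _organism_text(org: Optional[Organism]) -> str:
    if org is None:
        return "-"
    label = org.scientific_name or org.common_name or ""
    return f"{label} (taxid {org.taxid})" if label else f"taxid {org.taxid}"


def _features_text(participant: Participant) -> str:
    parts = []
    for f in participant.features:
        name = _cv_text(f.feature_type) if f.feature_type else "feature"
        ranges = ",".join(
            f"{r.start.coordinate if r.start.is_determinate() else '?'}-"
            f"{r.end.coordinate if r.end.is_determinate() else '?'}"
            for r in f.ranges
        )
        parts.append(f"{name} {ranges}".strip())
    return "; ".join(parts) or "-"


def _summary_rows(interaction: Interaction) -> list[tuple[str, str]]:
    rows = [
        ("Interaction type", _cv_text(interaction.interaction_type)),
        ("Negative", "yes" if interaction.is_negative else "no"),
        ("Participants", str(interaction.arity())),
    ]
    exp = interaction.experiment
    if exp is not None:
        rows.append(("Detection method", _cv_text(exp.detection_method)))
        if exp.host_organism is not None:
            rows.append(("Host organism", _organism_text(exp.host_organism)))
        pub = exp.publication
        if pub is not None:
            cite = pub.pubmed_id and f"pubmed:{pub.pubmed_id}" or pub.doi and f"doi:{pub.doi}" or pub.title or "-"
            rows.append(("Publication", cite))
    if interaction.confidences:
        rows.append(
            ("Confidence", "; ".join(f"{t.short_name}={v}" for t, v in interaction.confidences))
        )
    expansion = getattr(interaction, "complex_expansion", None)
    if expansion is not None:
        rows.append(("Complex expansion", _cv_text(expansion)))
    return rows


def write_html(interactions: Iterable[Interaction], title: str = "Molecular interactions") -> str:
    """Render interactions as one self-contained HTML document."""
    interactions = list(interactions)
    out: list[str] = []
    push = out.append
    push("<!DOCTYPE html>")
    push('<html lang="en"><head><meta charset="utf-8"/>')
    push(f"<title>{escape(title)}</title>")
    push(f"<style>{_STYLE}</style></head><body>")
    push(f"<h1>{escape(title)}</h1>")
    if not interactions:
        push('<p class="notice">This document contains zero interactions.</p>')
    for idx, interaction in enumerate(interactions, start=1):
        label = interaction.id or f"interaction {idx}"
        push(f"<h2>{escape(str(label))}</h2>")
        push('<dl class="summary">')
        for key, value in _summary_rows(interaction):
            push(f"<dt>{escape(key)}</dt><dd>{escape(value)}</dd>")
        push("</dl>")
        push("<table><thead><tr><th>Identifier</th><th>Biological role</th>"
             "<th>Experimental role</th><th>Organism</th><th>Features</th></tr></thead><tbody>")
        for participant in interaction.participants:
            cells = (
                participant.interactor.preferred_id.key(),
                _cv_text(participant.biological_role),
                _cv_text(participant.experimental_role),
                _organism_text(participant.interactor.organism),
                _features_text(participant),
            )
            push("<tr>" + "".join(f"<td>{escape(c)}</td>" for c in cells) + "</tr>")
        push("</tbody></table>")
    push("</body></html>")
    return "\n".join(out)
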