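"""Report writers for simulation tables and conduct recommendations.

Formats: aligned text (paste into a protocol document), CSV, markdown
pipe tables, and JSON for machine consumption.  Probabilities are shown
at 2 d.p. and operating-characteristic summaries at 1 d.p., matching the
precision a protocol table prints; underlying objects keep full
precision.
"""

from __future__ import annotations

import io
import json
from datetime import datetime, timezone

from .engine import Recommendation
from .simulate import OperatingCharacteristics

__all__ = ["render_report", "render_oc", "render_recommendation"]

FORMATS = ("text", "csv", "markdown", "json")


def _timestamp() -> str:
    return datetime.now(timezone.utc).isoformat(timespec="seconds")


def render_report(result, fmt: str = "text") -> str:
    """Render an OC table or a recommendation record in the given format."""
    if fmt not in FORMATS:
        raise ValueError(f"unknown format {fmt!r}; choose from {', '.join(FORMATS)}")
    if isinstance(result, OperatingCharacteristics):
        return render_oc(result, fmt)
    if isinstance(result, Recommendation):
        return render_recommendation(result, fmt)
    raise TypeError(f"cannot render object of type {type(result).__name__}")


def _oc_rows(oc: OperatingCharacteristics) -> list[list[str]]:
    K = len(oc.skeleton)
    return [
        ["Dose level"] + [str(k + 1) for k in range(K)],
        ["Skeleton"] + [f"{v:.2f}" for v in oc.skeleton],
        ["True DLT probability"] + [f"{v:.2f}" for v in oc.true_probs],
        ["% selected as MTD"] + [f"{v:.1f}" for v in oc.selection_pct],
        ["Mean # DLTs"] + [f"{v:.1f}" for v in oc.mean_dlts],
        ["Mean # patients"] + [f"{v:.1f}" for v in oc.mean_patients],
    ]


def render_oc(oc: OperatingCharacteristics, fmt: str = "text") -> str:
    """Operating-characteristics table plus safety-stop %, nsim and seed."""
    if fmt == "json":
        return json.dumps(
            {
                "skeleton": list(oc.skeleton),
                "true_probs": list(oc.true_probs),
                "selection_pct": list(oc.selection_pct),
                "mean_dlts": list(oc.mean_dlts),
                "mean_patients": list(oc.mean_patients),
                "safety_stop_pct": oc.safety_stop_pct,
                "nsim": oc.nsim,
                "seed": oc.seed,
            },
            indent=2,
        )
    rows = _oc_rows(oc)
    footer = [
        f"% trials stopped for safety: {oc.safety_stop_pct:.1f}",
        f"nsim: {oc.nsim}   seed: {oc.seed}",
    ]
    if fmt == "csv":
        buf = io.StringIO()
        for row in rows:
            buf.write(",".join(row) + "\n")
        buf.write(f"% stopped for safety,{oc.safety_stop_pct:.1f}\n")
        buf.write(f"nsim,{oc.nsim}\nseed,{oc.seed}\n")
        return buf.getvalue()
    if fmt == "markdown":
        header, *body = rows
        lines = ["| " + " | ".join(header) + " |"]
        lines.append("|" + "|".join(["---"] * len(header)) + "|")
        lines += ["| " + " | ".join(r) + " |" for r in body]
        return "\n".join(lines + footer)
    return _aligned(rows) + "\n" + "\n".join(footer)


def _aligned(rows: list[list[str]]) -> str:
    widths = [max(len(r[i]) for r in rows) for i in range(len(rows[0]))]
    return "\n".join(
        "  ".join(cell.ljust(w) for cell, w in zip(row, widths)) for row in rows
    )


def render_recommendation(rec: Recommendation, fmt: str = "text") -> str:
    """Conduct-mode report: estimates table headed by the audit timestamp."""
    post = rec.posterior
    K = len(post.p_hat)
    lo, hi = post.p1_interval
    if fmt == "json":
        return json.dumps(
            {
                "timestamp": rec.timestamp,
                "recommended_dose": rec.dose,
                "stop_reason": rec.stop_reason,
                "a_hat": post.a_hat,
                "p_hat": list(post.p_hat),
                "p1_interval_90": [lo, hi],
            },
            indent=2,
        )
    rows = [
        ["Dose level"] + [str(k + 1) for k in range(K)],
        ["Estimated DLT probability"] + [f"{v:.2f}" for v in post.p_hat],
    ]
    if rec.dose is not None:
        verdict = f"Recommended dose level: {rec.dose}"
    else:
        verdict = f"Trial stopped ({rec.stop_reason}): no dose recommended"
    safety = f"90% probability interval for DLT rate at dose 1: ({lo:.2f}, {hi:.2f})"
    if fmt == "csv":
        buf = io.StringIO()
        buf.write(f"timestamp,{rec.timestamp}\n")
        for row in rows:
            buf.write(",".join(row) + "\n")
        buf.write(f"recommended_dose,{'' if rec.dose is None else rec.dose}\n")
        buf.write(f"p1_interval_90,{lo:.4f},{hi:.4f}\n")
        return buf.getvalue()
    if fmt == "markdown":
        header, *body = rows
        lines = [rec.timestamp, ""]
        lines.append("| " + " | ".join(header) + " |")
        lines.append("|" + "|".join(["---"] * len(header)) + "|")
        lines += ["| " + " | ".join(r) + " |" for r in body]
        return "\n".join(lines + ["", verdict, safety])
    return "\n".join([rec.timestamp, _aligned(rows), verdict, safety])
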