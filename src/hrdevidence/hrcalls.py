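"""Dichotomise HR-prediction scores and assign CHORD gene subtypes.

Three tools' per-sample scores are consumed as inputs: the CHORD HRD
probability (with its BRCA1-type and BRCA2-type component probabilities),
the HRDetect probability, and the HRDsum genomic scar count.  Published
decision thresholds: CHORD > 0.5, HRDetect > 0.7 (strict), HRDsum >= 42.

For CHORD, an HRD sample is attributed to a BRCA1-like or BRCA2-like
deficiency pattern when the larger of the two component probabilities
reaches subtype_min_prob; otherwise the subtype is undetermined.  The rule
is a documented surrogate for CHORD's own undetermined criteria, which
depend on internal mutation counts not reproduced here.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
import logging
import math

import pandas as pd

log = logging.getLogger(__name__)

CHORD, HRDETECT, HRDSUM = "CHORD", "HRDetect", "HRDsum"
TOOLS = (CHORD, HRDETECT, HRDSUM)

HRD, HRP = "HRD", "HRP"
BRCA1_TYPE, BRCA2_TYPE = "BRCA1_type", "BRCA2_type"
UNDETERMINED, NOT_APPLICABLE = "undetermined", "not_applicable"

_SCORE_COLUMN = {
    CHORD: "chord_prob",
    HRDETECT: "hrdetect_prob",
    HRDSUM: "hrdsum_score",
}


@dataclass(frozen=True)
class ThresholdConfig:
    chord_cut: float = 0.5  # strict >
    hrdetect_cut: float = 0.7  # strict >
    hrdsum_cut: float = 42.0  # inclusive >=
    subtype_min_prob: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.chord_cut <= 1.0 and 0.0 <= self.hrdetect_cut <= 1.0):
            raise ValueError("probability cutoffs must lie in [0, 1]")
        if not math.isfinite(self.hrdsum_cut):
            raise ValueError("hrdsum cutoff must be finite")


@dataclass(frozen=True)
class HRStatusCall:
    tool: str
    status: str
    subtype: str = NOT_APPLICABLE


def _get(scores, name):
    v = scores.get(name) if hasattr(scores, "get") else getattr(scores, name, None)
    if v is None or (isinstance(v, float) and math.isnan(v)) or pd.isna(v):
        return None
    return float(v)


def call_hr_status(scores, tool: str, config: ThresholdConfig | None = None) -> HRStatusCall | None:
    """Dichotomise one sample's score for one tool; None if the score is missing."""
    cfg = config or ThresholdConfig()
    if tool not in TOOLS:
        raise ValueError(f"unknown tool {tool!r}; expected one of {TOOLS}")
    value = _get(scores, _SCORE_COLUMN[tool])
    if value is None:
        return None
    if tool == CHORD:
        status = HRD if value > cfg.chord_cut else HRP
    elif tool == HRDETECT:
        status = HRD if value > cfg.hrdetect_cut else HRP
    else:
        status = HRD if value >= cfg.hrdsum_cut else HRP
    return HRStatusCall(tool, status)


def call_chord_subtype(scores, config: ThresholdConfig | None = None) -> HRStatusCall | None:
    """CHORD call with BRCA1-type / BRCA2-type / undetermined attribution."""
    cfg = config or ThresholdConfig()
    base = call_hr_status(scores, CHORD, cfg)
    if base is None:
        return None
    p1 = _get(scores, "chord_brca1_prob")
    p2 = _get(scores, "chord_brca2_prob")
    if p1 is None or p2 is None:
        raise ValueError("CHORD subtype call requires both component probabilities")
    total = _get(scores, "chord_prob")
    if p1 + p2 > total + 1e-9:
        raise ValueError(
            f"component probabilities ({p1} + {p2}) exceed the HRD probability {total}"
        )
    if base.status == HRP:
        return HRStatusCall(CHORD, HRP, NOT_APPLICABLE)
    top = max(p1, p2)
    if top < cfg.subtype_min_prob or p1 == p2:
        return HRStatusCall(CHORD, HRD, UNDETERMINED)
    return HRStatusCall(CHORD, HRD, BRCA1_TYPE if p1 > p2 else BRCA2_TYPE)


def call_cohort(
    scores: pd.DataFrame,
    tools: str | list[str] = "all",
    config: ThresholdConfig | None = None,
) -> pd.DataFrame:
    """Call every patient for the requested tool(s).

    Output columns: patient_id, tool, status, subtype.  Patients with a
    missing score for a tool are silently omitted for that tool.
    """
    cfg = config or ThresholdConfig()
    wanted = list(TOOLS) if tools == "all" else ([tools] if isinstance(tools, str) else list(tools))
    rows = []
    for _, r in scores.iterrows():
        for tool in wanted:
            call = (
                call_chord_subtype(r, cfg) if tool == CHORD else call_hr_status(r, tool, cfg)
            )
            if call is None:
                continue
            rows.append(
                {
                    "patient_id": str(r["patient_id"]),
                    "tool": call.tool,
                    "status": call.status,
                    "subtype": call.subtype,
                }
            )
    return pd.DataFrame(rows, columns=["patient_id", "tool", "status", "subtype"])


def concordance_table(calls: pd.DataFrame) -> pd.DataFrame:
    """Pairwise agreement between tools over their shared patients.

    One row per tool pair: counts of joint HRD calls, joint HRP calls,
    discordant calls and the overall agreement fraction.
    """
    tools = sorted(calls["tool"].unique())
    if len(tools) < 2:
        raise ValueError("concordance requires calls from at least two tools")
    wide = calls.pivot(index="patient_id", columns="tool", values="status")
    rows = []
    for a, b in combinations(tools, 2):
        both = wide[[a, b]].dropna()
        if both.empty:
            log.warning("no overlapping patients for %s vs %s", a, b)
            rows.append(
                {"tool_a": a, "tool_b": b, "n": 0, "both_hrd": 0, "both_hrp": 0,
                 "discordant": 0, "agreement": float("nan")}
            )
            continue
        both_hrd = int(((both[a] == HRD) & (both[b] == HRD)).sum())
        both_hrp = int(((both[a] == HRP) & (both[b] == HRP)).sum())
        disc = len(both) - both_hrd - both_hrp
        rows.append(
            {
                "tool_a": a,
                "tool_b": b,
                "n": len(both),
                "both_hrd": both_hrd,
                "both_hrp": both_hrp,
                "discordant": disc,
                "agreement": (both_hrd + both_hrp) / len(both),
            }
        )
    return pd.DataFrame(rows)
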