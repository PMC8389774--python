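"""Combined diagnostics report with a reliability verdict.

Given an energy table (or a synthetic stream recipe), compute σ_IE, the
IE and C2 entropies and their gap, a block-convergence table, the
statistical inefficiency and Gaussianity statistics, and issue a
three-tier verdict on which estimator — if either — can be trusted:

* tier 1, σ_IE below ~15 kJ/mol: both IE and C2 usable (below
  ~10 kJ/mol they should agree within a few kJ/mol);
* tier 2, 15–25 kJ/mol: the IE exponential average cannot be converged
  at practical sample sizes — use C2 only;
* tier 3, above 25 kJ/mol: C2 still converges but the value is most
  likely grossly overestimated — neither estimate is reliable.

Thresholds are config-overridable; the defaults encode the published
reliability boundaries.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from typing import Dict, List, Optional

import numpy as np

from .estimators import c2_entropy, ie_entropy
from .io import read_energy_table, rmsd_below, filter_frames
from .series import EnergySeries
from .series_analysis import (
    convergence_curve,
    gaussianity_report,
    statistical_inefficiency,
)
from .synthetic_data import StreamSpec, generate

__all__ = ["run_report", "DEFAULT_THRESHOLDS", "verdict_tier"]

#: σ_IE verdict boundaries in kJ/mol: below ``agree`` IE and C2 should
#: coincide; above ``ie_limit`` IE cannot be converged; above
#: ``c2_limit`` C2 is unrealistically large.
DEFAULT_THRESHOLDS: Dict[str, float] = {
    "agree": 10.0,
    "ie_limit": 15.0,
    "c2_limit": 25.0,
}

_TIER_TEXT = {
    1: "both IE and C2 usable",
    2: "IE unconvergable; use C2 only",
    3: "neither reliable: C2 converges but is grossly overestimated",
}


def verdict_tier(sigma: float, thresholds: Optional[Dict[str, float]] = None) -> int:
    """Map σ_IE (kJ/mol) to verdict tier 1/2/3."""
    t = {**DEFAULT_THRESHOLDS, **(thresholds or {})}
    if sigma < t["ie_limit"]:
        return 1
    if sigma < t["c2_limit"]:
        return 2
    return 3


def _validate_config(config: dict) -> List[str]:
    errors = []
    has_input = "input" in config
    has_synth = "synthetic" in config
    if has_input == has_synth:
        errors.append("config must name exactly one of 'input' or 'synthetic'")
    if has_input and not isinstance(config["input"], (str, dict)):
        errors.append("'input' must be a path or a {path, ...} mapping")
    if has_synth and not isinstance(config["synthetic"], dict):
        errors.append("'synthetic' must be a mapping of StreamSpec fields")
    bs = config.get("block_sizes")
    if bs is not None:
        if not isinstance(bs, (list, tuple)) or not all(
            isinstance(b, int) and b >= 2 for b in bs
        ):
            errors.append("'block_sizes' must be a list of integers >= 2")
    thr = config.get("thresholds")
    if thr is not None and not isinstance(thr, dict):
        errors.append("'thresholds' must be a mapping")
    return errors


def _load_series(config: dict) -> EnergySeries:
    if "synthetic" in config:
        spec = StreamSpec(**config["synthetic"])
        return generate(spec)
    inp = config["input"]
    if isinstance(inp, str):
        return read_energy_table(inp)
    series = read_energy_table(
        inp["path"],
        temperature=inp.get("temperature", 300.0),
        frame_spacing=inp.get("frame_spacing"),
    )
    if "max_rmsd" in inp:
        series, _ = filter_frames(series, rmsd_below(inp["max_rmsd"]))
    return series


def run_report(config: dict) -> dict:
    """Full diagnostics for one energy series, as a JSON-safe dict.

    The config names either an ``input`` table or a ``synthetic`` stream
    spec, plus optional ``block_sizes``, ``thresholds`` and ``n_bins``.
    All validation errors are collected and raised together before any
    computation starts; identical config (and seed, for synthetic
    input) always produces identical output.
    """
    errors = _validate_config(config)
    if errors:
        raise ValueError("invalid report config:\n  - " + "\n  - ".join(errors))
    series = _load_series(config)
    n = len(series)

    ie = ie_entropy(series)
    c2 = c2_entropy(series)
    sigma = c2.sigma_hat

    block_sizes = config.get("block_sizes")
    if block_sizes is None:
        block_sizes = [b for b in (100, 1000, 10_000, 100_000) if b <= n // 2] or (
            [max(2, n // 4)] if n >= 8 else []
        )
    blocks = []
    for curve_name in ("IE", "C2"):
        if not block_sizes:
            break
        curve = convergence_curve(series, block_sizes, curve_name)
        for (bn, est, se, nb) in curve.points:
            blocks.append(
                {"estimator": curve_name, "N": bn, "estimate": est,
                 "std_error": se, "n_batches": nb}
            )

    g = statistical_inefficiency(series) if n >= 100 and sigma > 0 else None
    gauss = gaussianity_report(series, config.get("n_bins", 50)) if n >= 100 else None

    thresholds = {**DEFAULT_THRESHOLDS, **(config.get("thresholds") or {})}
    tier = verdict_tier(sigma, thresholds)

    report = {
        "n_frames": n,
        "temperature_K": series.temperature,
        "sigma_ie": sigma,
        "minus_T_dS_IE": ie.minus_T_delta_S,
        "minus_T_dS_C2": c2.minus_T_delta_S,
        "ie_c2_gap": c2.minus_T_delta_S - ie.minus_T_delta_S,
        "block_convergence": blocks,
        "statistical_inefficiency": g,
        "effective_samples": (n / g) if g else None,
        "skewness": gauss.skewness if gauss else None,
        "excess_kurtosis": gauss.excess_kurtosis if gauss else None,
        "thresholds": thresholds,
        "verdict": {"tier": tier, "text": _TIER_TEXT[tier]},
        "config": {
            k: (dict(asdict(StreamSpec(**v))) if k == "synthetic" and isinstance(v, dict) else v)
            for k, v in config.items()
        },
    }
    # ensure JSON-safe output
    json.dumps(report)
    return report
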