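"""Per-round dependent variables and all file output.

Six quantities are tracked each round: the distribution of citizen beliefs
(median with symmetric quantile bands at 10-percentage-point steps), mean
local-network *purity* (the echo-chamber indicator), counts of accepted
communications and of cue-based rejections split into correct rejections vs
false positives, the cumulative percentage of citizens ever trained, the
population mean of current cue sensitivity, and mean confidence P(H|E).
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "QUANTILE_STEPS",
    "RoundMetrics",
    "purity",
    "mean_purity",
    "belief_quantiles",
    "collect_round_metrics",
    "metrics_frame",
    "snapshot_frame",
    "edges_frame",
    "write_outputs",
]

#: Quantile levels recorded around the median (±10%-step bands).
QUANTILE_STEPS = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)


@dataclass(frozen=True)
class RoundMetrics:
    """All dependent variables for one round."""

    round: int
    q10: float
    q20: float
    q30: float
    q40: float
    median: float
    q60: float
    q70: float
    q80: float
    q90: float
    mean_purity: float
    n_communications: int
    n_correct_rejections: int
    n_false_positives: int
    pct_ever_trained: float
    mean_current_mcs: float
    mean_confidence: float


def purity(citizen, population: dict) -> float | None:
    """Local agreement of one citizen with their direct peers.

    1 − mean squared belief difference over directly connected peers: 1 is
    complete agreement, 0 maximal disagreement. ``None`` when the citizen
    has no peers (excluded from the population mean).
    """
    if not citizen.peers:
        return None
    mu = citizen.belief.mu_own
    sq = [(mu - population[p].belief.mu_own) ** 2 for p in citizen.peers]
    return 1.0 - sum(sq) / len(sq)


def mean_purity(citizens: list, population: dict) -> float:
    """Mean purity over citizens that have at least one peer (NaN if none)."""
    values = [p for c in citizens if (p := purity(c, population)) is not None]
    return float(np.mean(values)) if values else math.nan


def belief_quantiles(mu_values) -> dict[str, float]:
    """Median and ±10%-step quantiles of the belief values."""
    mu = np.asarray(list(mu_values), dtype=float)
    if mu.size == 0:
        raise ValueError("belief_quantiles requires a non-empty population")
    qs = np.quantile(mu, QUANTILE_STEPS)
    names = ["q10", "q20", "q30", "q40", "median", "q60", "q70", "q80", "q90"]
    return dict(zip(names, map(float, qs)))


def collect_round_metrics(
    round_index: int,
    citizens: list,
    population: dict,
    n_communications: int,
    n_correct_rejections: int,
    n_false_positives: int,
) -> RoundMetrics:
    """Assemble the RoundMetrics record from the end-of-round state."""
    quantiles = belief_quantiles(c.belief.mu_own for c in citizens)
    n = len(citizens)
    return RoundMetrics(
        round=round_index,
        **quantiles,
        mean_purity=mean_purity(citizens, population),
        n_communications=n_communications,
        n_correct_rejections=n_correct_rejections,
        n_false_positives=n_false_positives,
        pct_ever_trained=100.0 * sum(c.sensitivity.ever_trained for c in citizens) / n,
        mean_current_mcs=float(np.mean([c.sensitivity.current_mcs for c in citizens])),
        mean_confidence=float(np.mean([c.belief.confidence for c in citizens])),
    )


def metrics_frame(series: list[RoundMetrics]) -> pd.DataFrame:
    """One row per round; header-only when the series is empty."""
    if not series:
        return pd.DataFrame(columns=list(RoundMetrics.__dataclass_fields__))
    return pd.DataFrame([asdict(m) for m in series])


def snapshot_frame(citizens: list) -> pd.DataFrame:
    """Per-citizen state snapshot."""
    return pd.DataFrame(
        {
            "id": [c.id for c in citizens],
            "mu_own": [c.belief.mu_own for c in citizens],
            "sigma_own": [c.belief.sigma_own for c in citizens],
            "confidence": [c.belief.confidence for c in citizens],
            "current_mcs": [c.sensitivity.current_mcs for c in citizens],
            "base_mcs": [c.sensitivity.base_mcs for c in citizens],
            "ever_trained": [c.sensitivity.ever_trained for c in citizens],
            "n_peers": [len(c.peers) for c in citizens],
            "declaring": [c.current_post is not None for c in citizens],
        }
    )


def edges_frame(citizens: list, round_index: int) -> pd.DataFrame:
    """Undirected edge list (each link once, id_a < id_b)."""
    edges = sorted(
        {(min(c.id, p), max(c.id, p)) for c in citizens for p in c.peers}
    )
    return pd.DataFrame(
        {
            "round": [round_index] * len(edges),
            "id_a": [a for a, _ in edges],
            "id_b": [b for _, b in edges],
        }
    )


def write_outputs(result, out_dir) -> dict[str, Path]:
    """Serialize one run: metrics, final snapshot, edge list, config echo.

    Returns the paths written, keyed by artefact name. CSVs are RFC-4180,
    UTF-8, '.' decimal.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "metrics": out / "metrics.csv",
        "snapshot": out / "citizens.csv",
        "edges": out / "edges.csv",
        "config": out / "config.json",
    }
    metrics_frame(result.metrics).to_csv(paths["metrics"], index=False)
    snapshot_frame(result.citizens).to_csv(paths["snapshot"], index=False)
    edges_frame(result.citizens, result.final_round).to_csv(paths["edges"], index=False)
    result.config.to_json(paths["config"])
    for rnd, frame in getattr(result, "snapshots", {}).items():
        path = out / f"citizens_round_{rnd:03d}.csv"
        frame.to_csv(path, index=False)
        paths[f"snapshot_round_{rnd}"] = path
    return paths
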