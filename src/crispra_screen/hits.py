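"""ESP scoring, first-pass filtering, trajectory classification and hit
ranking.

The combined ESP score is (casTLE-Effect + casTLE-Score)/pValue, with the
p-value floored at the smallest value a permutation test can produce.  The
first-pass filter retains genes with effect > 2, score > 2 and p < 0.05
(strict inequalities, as printed) that lie in the membrane/secreted
proteome and are not blacklisted.  A called hit must additionally show a
positive ESP trajectory over the consecutive selection rounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HitConfig",
    "esp_score",
    "first_pass_filter",
    "classify_trajectory",
    "rank_hits",
    "call_hits",
    "MEMBRANE_CLASSES",
]

MEMBRANE_CLASSES = frozenset(
    {"TM1-membrane", "TM2+-membrane", "membrane", "secreted"}
)

EFFECT_CUTOFF = 2.0
SCORE_CUTOFF = 2.0
P_CUTOFF = 0.05


@dataclass(frozen=True)
class HitConfig:
    n_perm: int = 10_000
    trajectory_tolerance: float = 0.1  # relative dip permitted per step
    effect_cutoff: float = EFFECT_CUTOFF
    score_cutoff: float = SCORE_CUTOFF
    p_cutoff: float = P_CUTOFF
    blacklist: frozenset = field(default_factory=frozenset)

    @property
    def p_floor(self) -> float:
        return 1.0 / (self.n_perm + 1)


def esp_score(effect, score, p_value, p_floor: float = 1.0 / 10_001):
    """Combined ESP score (effect + score) / max(p, p_floor)."""
    p = np.maximum(np.asarray(p_value, dtype=float), p_floor)
    out = (np.asarray(effect, dtype=float) + np.asarray(score, dtype=float)) / p
    return float(out) if np.isscalar(effect) else out


def first_pass_filter(
    results: pd.DataFrame,
    annotation: Mapping[str, str] | None,
    blacklist: Iterable[str] = (),
    config: HitConfig | None = None,
) -> pd.DataFrame:
    """Apply the first-pass cut-offs plus annotation and blacklist screens.

    Genes missing from ``annotation`` are class "other" and are removed,
    since candidates outside the secreted and membrane proteome are not
    plausible bead-binding receptors.
    """
    cfg = config or HitConfig()
    annotation = annotation or {}
    blacklist = set(blacklist) | set(cfg.blacklist)
    classes = results["gene"].map(lambda g: annotation.get(g, "other"))
    keep = (
        (results["effect"] > cfg.effect_cutoff)
        & (results["score"] > cfg.score_cutoff)
        & (results["p_value"] < cfg.p_cutoff)
        & classes.isin(MEMBRANE_CLASSES)
        & ~results["gene"].isin(blacklist)
    )
    out = results[keep].copy()
    out["annotation_class"] = classes[keep]
    return out


def classify_trajectory(
    esp_values: Sequence[float], tolerance: float = 0.1
) -> str:
    """Classify a per-round ESP trajectory as positive, negative or flat.

    The tolerance is a noise band: round-to-round dips of at most
    ``tolerance`` of the previous magnitude are treated as sampling noise.
    A constant trajectory is flat.  A trajectory is positive when every
    step is nondecreasing within the band and the final value has not
    fallen below the first by more than the band (strongly enriched genes
    can saturate the score, so the terminal comparison honors the same
    noise band as the steps).  It is negative when the final value lies
    below the first.  Anything else (e.g. a deep transient dip followed by
    recovery) is flat.
    """
    esp = np.asarray(esp_values, dtype=float)
    if esp.size < 2:
        raise ValueError(
            "trajectory classification needs >= 2 rounds; "
            "use rank-only mode for single-round screens"
        )
    if np.all(esp == esp[0]):
        return "flat"
    steps_ok = all(
        esp[i + 1] >= esp[i] - tolerance * abs(esp[i]) for i in range(esp.size - 1)
    )
    if steps_ok and esp[-1] >= esp[0] - tolerance * abs(esp[0]):
        return "positive"
    if esp[-1] < esp[0]:
        return "negative"
    return "flat"


def rank_hits(results: pd.DataFrame, esp_column: str = "esp") -> pd.DataFrame:
    """Rank by descending ESP; ties broken by higher score, then gene_id."""
    out = results.sort_values(
        by=[esp_column, "score", "gene"],
        ascending=[False, False, True],
        ignore_index=True,
    )
    out["final_rank"] = np.arange(1, len(out) + 1)
    return out


def call_hits(
    per_round_results: Mapping[str, pd.DataFrame],
    annotation: Mapping[str, str] | None,
    blacklist: Iterable[str] = (),
    config: HitConfig | None = None,
) -> pd.DataFrame:
    """Combine per-round gene results into ranked hit calls.

    ``per_round_results`` maps round sample names (in selection order) to
    gene result tables.  The first-pass filter is applied to the final
    round; trajectories are computed over all rounds; called hits are
    filtered genes with a positive trajectory, ranked by final-round ESP.
    """
    cfg = config or HitConfig()
    rounds = list(per_round_results)
    if not rounds:
        return pd.DataFrame(
            columns=["gene", "esp", "trajectory", "passes_first_pass", "called"]
        )
    final = rounds[-1]

    merged: pd.DataFrame | None = None
    for r in rounds:
        t = per_round_results[r][
            ["gene", "effect", "score", "p_value"]
        ].copy()
        t[f"esp_{r}"] = esp_score(
            t["effect"].to_numpy(), t["score"].to_numpy(), t["p_value"].to_numpy(),
            p_floor=cfg.p_floor,
        )
        t = t.rename(
            columns={c: f"{c}_{r}" for c in ("effect", "score", "p_value")}
        )
        merged = t if merged is None else merged.merge(t, on="gene", how="outer")
    if merged is None or merged.empty:
        return pd.DataFrame(
            columns=["gene", "esp", "trajectory", "passes_first_pass", "called"]
        )

    esp_cols = [f"esp_{r}" for r in rounds]
    if len(rounds) >= 2:
        merged["trajectory"] = [
            classify_trajectory(row, cfg.trajectory_tolerance)
            for row in merged[esp_cols].to_numpy()
        ]
    else:
        merged["trajectory"] = "undefined"

    final_results = per_round_results[final]
    passed = set(
        first_pass_filter(final_results, annotation, blacklist, cfg)["gene"]
    )
    merged["passes_first_pass"] = merged["gene"].isin(passed)
    if len(rounds) >= 2:
        merged["called"] = merged["passes_first_pass"] & (
            merged["trajectory"] == "positive"
        )
    else:
        merged["called"] = merged["passes_first_pass"]

    merged["esp"] = merged[f"esp_{final}"]
    merged["score"] = merged[f"score_{final}"]
    ranked = rank_hits(merged, esp_column="esp")
    # ranks are assigned over called hits first, then the remainder
    ranked = pd.concat(
        [ranked[ranked["called"]], ranked[~ranked["called"]]], ignore_index=True
    )
    ranked["final_rank"] = np.arange(1, len(ranked) + 1)
    return ranked
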