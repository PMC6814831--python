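"""Biotic-resistance scores from per-capita, preference and fecundity traits.

A resident predator's potential to resist an invading prey species is
summarised as the product

    BR = (FRR_i / FRR_n) * FE * alpha_i

of (i) its functional response ratio towards the invader relative to the
native prey (per-capita impact skew), (ii) a fecundity proxy FE for the
numerical response (clutch weight per female body weight per day, taken
from the literature — not computed here), and (iii) its mean Manly
preference for the invader across availabilities.  Predators are compared
pairwise through the Relative Biotic Resistance RBR = BR1 / BR2, with 1
meaning equivalence and values above 1 meaning predator 1 exerts the
stronger resistance.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = [
    "PredatorProfile",
    "relative_frr",
    "biotic_resistance_score",
    "relative_biotic_resistance",
    "BRResult",
    "compute_br",
    "triplot_data",
    "plot_triplot",
]


@dataclass(frozen=True)
class PredatorProfile:
    """Traits entering the BR score for one predator."""

    predator: str
    frr_invader: float
    frr_native: float
    fecundity: float
    mean_alpha: float

    def __post_init__(self):
        if self.frr_invader <= 0 or self.frr_native <= 0:
            raise ValueError("functional response ratios must be positive")
        if self.fecundity <= 0:
            raise ValueError("fecundity proxy must be positive")
        if not 0 <= self.mean_alpha <= 1:
            raise ValueError("mean preference must lie in [0, 1]")


def relative_frr(frr_invader: float, frr_native: float) -> float:
    """Per-capita impact skew towards the invader: FRR_i / FRR_n."""
    if frr_invader <= 0 or frr_native <= 0:
        raise ValueError("functional response ratios must be positive")
    return frr_invader / frr_native


def biotic_resistance_score(profile: PredatorProfile) -> float:
    """BR = (FRR_i / FRR_n) * FE * mean preference."""
    return relative_frr(profile.frr_invader, profile.frr_native) * profile.fecundity * profile.mean_alpha


def relative_biotic_resistance(br1: float, br2: float) -> float:
    """RBR = BR1 / BR2; above 1 means predator 1 resists more strongly."""
    if br1 <= 0 or br2 <= 0:
        raise ValueError("BR scores must be positive")
    return br1 / br2


@dataclass
class BRResult:
    """BR scores and pairwise comparisons for a set of predators."""

    per_predator: pd.DataFrame  # predator, relative_frr, fecundity, mean_alpha, br
    pairwise: pd.DataFrame  # predator_1, predator_2, per-predator columns, rbr

    def rbr_matrix(self) -> pd.DataFrame:
        preds = list(self.per_predator["predator"])
        br = dict(zip(preds, self.per_predator["br"]))
        mat = pd.DataFrame(
            [[br[p] / br[q] for q in preds] for p in preds], index=preds, columns=preds
        )
        return mat


def compute_br(profiles: list[PredatorProfile], report_decimals: int | None = 3) -> BRResult:
    """Score every predator and enumerate ordered pairwise RBR comparisons.

    Predators are ordered lexicographically by label (deterministic
    tie-break); the pairwise table lists each unordered pair once, in that
    label order.

    ``report_decimals`` controls the convention for the pairwise ratios:
    published BR tables quote scores at a fixed precision and take RBR as
    the ratio of the quoted scores, so by default each RBR is the ratio of
    the BRs rounded to 3 decimals (pass ``None`` for full-precision
    ratios).  Antisymmetry RBR(p,q) * RBR(q,p) = 1 holds either way.
    """
    if not profiles:
        raise ValueError("at least one predator profile is required")
    profiles = sorted(profiles, key=lambda p: p.predator)
    rows = []
    for p in profiles:
        rows.append(
            {
                "predator": p.predator,
                "frr_invader": p.frr_invader,
                "frr_native": p.frr_native,
                "relative_frr": relative_frr(p.frr_invader, p.frr_native),
                "fecundity": p.fecundity,
                "mean_alpha": p.mean_alpha,
                "br": biotic_resistance_score(p),
            }
        )
    per_predator = pd.DataFrame(rows)
    br = dict(zip(per_predator["predator"], per_predator["br"]))
    if report_decimals is not None:
        br = {k: round(v, report_decimals) for k, v in br.items()}
    info = per_predator.set_index("predator")
    pair_rows = []
    for p1, p2 in combinations(per_predator["predator"], 2):
        pair_rows.append(
            {
                "predator_1": p1,
                "predator_2": p2,
                "relative_frr_1": info.loc[p1, "relative_frr"],
                "relative_frr_2": info.loc[p2, "relative_frr"],
                "fecundity_1": info.loc[p1, "fecundity"],
                "fecundity_2": info.loc[p2, "fecundity"],
                "mean_alpha_1": info.loc[p1, "mean_alpha"],
                "mean_alpha_2": info.loc[p2, "mean_alpha"],
                "br_1": br[p1],
                "br_2": br[p2],
                "rbr": relative_biotic_resistance(br[p1], br[p2]),
            }
        )
    return BRResult(per_predator=per_predator, pairwise=pd.DataFrame(pair_rows))


def triplot_data(result: BRResult) -> pd.DataFrame:
    """Plottable per-predator coordinates: the three BR axes plus rank.

    Rank 1 is the strongest resistor (BR descending); ties break on the
    predator label so output is deterministic.
    """
    df = result.per_predator[
        ["predator", "relative_frr", "fecundity", "mean_alpha", "br"]
    ].copy()
    df = df.sort_values(["br", "predator"], ascending=[False, True], kind="stable")
    df["rank"] = range(1, len(df) + 1)
    return df.reset_index(drop=True)


def plot_triplot(result: BRResult, ax=None):
    """Scatter of relative FRR vs fecundity, point size/colour by BR.

    Marker area scales with mean invader preference; colour ramps with the
    BR score so stronger resistors read towards the top right in red.
    """
    import matplotlib.pyplot as plt

    data = triplot_data(result)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    sc = ax.scatter(
        data["relative_frr"],
        data["fecundity"],
        s=200 * data["mean_alpha"] + 20,
        c=data["br"],
        cmap="coolwarm",
        edgecolor="black",
    )
    for _, row in data.iterrows():
        ax.annotate(
            f"{row['predator']} ({row['br']:.3f})",
            (row["relative_frr"], row["fecundity"]),
            textcoords="offset points",
            xytext=(6, 6),
            fontsize=8,
        )
    ax.set_xlabel("Relative FRR (invader / native)")
    ax.set_ylabel("Fecundity proxy FE")
    plt.colorbar(sc, ax=ax, label="Biotic Resistance")
    return ax
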