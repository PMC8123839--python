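"""Clarke Error Grid classification of paired glucose measurements.

The Clarke Error Grid partitions the (reference, device) plane — reference
glucose on the x-axis, device (CGM) glucose on the y-axis — into five zones
grading the clinical consequence of measurement error:

* **A** — clinically accurate: within 20% of the reference, or both values
  hypoglycemic (< 70 mg/dL); leads to correct treatment decisions.
* **B** — benign error: > 20% deviation but treatment would still be
  appropriate or omitted harmlessly.
* **C** — overcorrection: would prompt treating an acceptable glucose.
* **D** — dangerous failure to detect: hypo- or hyperglycemia read as
  acceptable.
* **E** — erroneous treatment: hypoglycemia read as hyperglycemia or vice
  versa.

Zone A is "clinically accurate"; zones A+B together are "clinically
acceptable".  The classifier below is the standard piecewise formulation of
the original 1987 grid, evaluated in a fixed precedence order
(A, E, C, D, else B) so boundary ties resolve deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .metrics import UndefinedStatisticError, round_half_up
from .pairing import MatchedPair

ZONES = ("A", "B", "C", "D", "E")


def clarke_zones(reference, device) -> np.ndarray:
    """Vectorised zone labels for arrays of (reference, device) mg/dL values."""
    ref = np.asarray(reference, dtype=float)
    dev = np.asarray(device, dtype=float)
    if ref.shape != dev.shape:
        raise ValueError("reference and device arrays must have the same shape")
    if np.any(ref <= 0) or np.any(dev <= 0) or np.any(ref >= 1000) or np.any(dev >= 1000):
        raise ValueError("glucose values must lie in (0, 1000) mg/dL")

    ad = np.abs(dev - ref)
    zone_a = ((ref < 70) & (dev < 70)) | (ad <= 0.2 * ref)
    zone_e = ((ref >= 180) & (dev <= 70)) | ((ref <= 70) & (dev >= 180))
    zone_c = ((70 <= ref) & (ref <= 290) & (dev >= ref + 110)) | (
        (130 <= ref) & (ref <= 180) & (dev <= (7.0 / 5.0) * ref - 182)
    )
    zone_d = (
        ((ref >= 240) & (70 <= dev) & (dev <= 180))
        | ((ref <= 175.0 / 3.0) & (70 <= dev) & (dev <= 180))
        | ((175.0 / 3.0 <= ref) & (ref <= 70) & (dev >= (6.0 / 5.0) * ref))
    )
    # first match wins: A, E, C, D, else B
    return np.select([zone_a, zone_e, zone_c, zone_d], ["A", "E", "C", "D"], default="B")


def clarke_zone(reference: float, device: float) -> str:
    """Zone label for a single (reference, device) pair, mg/dL."""
    return str(clarke_zones([reference], [device])[0])


@dataclass(frozen=True)
class ClarkeResult:
    """Per-pair zone labels with the zone count/proportion summary."""

    zones: list[str]
    counts: dict[str, int]
    proportions: dict[str, float]  # percent, unrounded
    pct_clinically_accurate: float  # zone A
    pct_clinically_acceptable: float  # zones A+B

    @property
    def n(self) -> int:
        return len(self.zones)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "counts": dict(self.counts),
            "proportions_pct": dict(self.proportions),
            "pct_clinically_accurate": self.pct_clinically_accurate,
            "pct_clinically_acceptable": self.pct_clinically_acceptable,
            "pct_clinically_accurate_rounded": round_half_up(self.pct_clinically_accurate),
            "pct_clinically_acceptable_rounded": round_half_up(self.pct_clinically_acceptable),
        }


def clarke_summary(pairs: list[MatchedPair]) -> ClarkeResult:
    """Classify every pair (serum = reference, CGM = device) and summarise."""
    if not pairs:
        raise UndefinedStatisticError("Clarke summary undefined for an empty set of pairs")
    ref = np.array([p.serum_value for p in pairs])
    dev = np.array([p.cgm_value for p in pairs])
    labels = clarke_zones(ref, dev)
    n = len(labels)
    counts = {z: int(np.sum(labels == z)) for z in ZONES}
    props = {z: 100.0 * counts[z] / n for z in ZONES}
    return ClarkeResult(
        zones=[str(z) for z in labels],
        counts=counts,
        proportions=props,
        pct_clinically_accurate=props["A"],
        pct_clinically_acceptable=props["A"] + props["B"],
    )


def grid_geometry() -> list[tuple[str, np.ndarray]]:
    """Zone-boundary polylines over [0, 400]² mg/dL for plotting.

    Returns (name, vertices) pairs where vertices is an (n, 2) array of
    (reference, device) points.  The segments are consistent with
    :func:`clarke_zone`: interior points of every drawn region classify to
    that region's label.
    """
    x70 = 175.0 / 3.0  # where device = 70 meets the upper-A line device = 1.2·ref
    seg = lambda name, pts: (name, np.array(pts, dtype=float))
    return [
        seg("identity", [(0, 0), (400, 400)]),
        seg("upper_A_horizontal", [(0, 70), (x70, 70)]),
        seg("upper_A_line", [(x70, 70), (400 / 1.2, 400)]),  # device = 1.2·ref
        seg("lower_A_vertical", [(70, 0), (70, 56)]),
        seg("lower_A_line", [(70, 56), (400, 320)]),  # device = 0.8·ref
        seg("upper_B_vertical", [(70, 84), (70, 400)]),
        seg("upper_C_horizontal", [(0, 180), (70, 180)]),
        seg("upper_C_line", [(70, 180), (290, 400)]),  # device = ref + 110
        seg("lower_C_line", [(130, 0), (180, 70)]),  # device = 1.4·ref − 182
        seg("lower_E_vertical", [(180, 0), (180, 70)]),
        seg("lower_E_horizontal", [(180, 70), (400, 70)]),
        seg("right_D_vertical", [(240, 70), (240, 180)]),
        seg("right_D_horizontal", [(240, 180), (400, 180)]),
    ]


_ZONE_LABEL_POSITIONS = {
    "A": (320, 320),
    "B": (250, 330),
    "C": (160, 370),
    "D": (25, 125),
    "E": (25, 320),
}
_ZONE_LABEL_POSITIONS_2 = {"B": (370, 230), "C": (160, 15), "D": (370, 120), "E": (370, 25)}


def plot_clarke(pairs: list[MatchedPair], path, title: str = "Clarke Error Grid") -> None:
    """Scatter the pairs over the grid boundaries and save to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    for name, pts in grid_geometry():
        style = dict(color="black", lw=1, ls=":" if name == "identity" else "-")
        ax.plot(pts[:, 0], pts[:, 1], **style)
    for labels in (_ZONE_LABEL_POSITIONS, _ZONE_LABEL_POSITIONS_2):
        for z, (x, y) in labels.items():
            ax.text(x, y, z, fontsize=12, ha="center", va="center")
    ax.scatter(
        [p.serum_value for p in pairs],
        [p.cgm_value for p in pairs],
        s=12,
        c="tab:blue",
        alpha=0.6,
        edgecolors="none",
    )
    ax.set_xlim(0, 400)
    ax.set_ylim(0, 400)
    ax.set_xlabel("Serum glucose (mg/dL)")
    ax.set_ylabel("CGM glucose (mg/dL)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
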