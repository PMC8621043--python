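"""Summary products over a tracking-results table: velocity histogram,
direction fractions, velocity-class fractions and the closest-approach
cross-section with co-location multiplicities.

Flagged transits (degenerate, above the resolution limit, error bound over
ceiling) are excluded from the statistics but their count is reported, so
the exclusion is visible rather than silent.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = ["Summary", "summarize", "VELOCITY_CLASS_EDGES"]

logger = logging.getLogger(__name__)

#: speed-class boundaries (m/s) mirroring the fibre-diameter census classes
VELOCITY_CLASS_EDGES = (0.5, 1.0)


@dataclass(frozen=True)
class Summary:
    n_total: int
    n_flagged: int
    speed_histogram: pd.DataFrame  # bin_left_mps, bin_right_mps, count
    direction_fractions: dict[str, float]
    class_fractions: dict[str, float]  # lt_0.5 / 0.5_to_1 / gt_1
    approach_points: pd.DataFrame  # y_um, z_um, multiplicity

    def to_files(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.speed_histogram.to_csv(outdir / "speed_histogram.tsv", sep="\t", index=False)
        self.approach_points.to_csv(outdir / "approach_points.tsv", sep="\t", index=False)
        (outdir / "summary.json").write_text(
            json.dumps(
                {
                    "n_total": self.n_total,
                    "n_flagged": self.n_flagged,
                    "direction_fractions": self.direction_fractions,
                    "class_fractions": self.class_fractions,
                },
                indent=2,
            )
            + "\n"
        )


def _colocate(points: np.ndarray, radius_um: float) -> pd.DataFrame:
    """Greedy co-location clustering: count points within ``radius_um`` of a
    cluster seed as one entry with a multiplicity."""
    seeds: list[np.ndarray] = []
    counts: list[int] = []
    for p in points:
        for k, s in enumerate(seeds):
            if float(np.hypot(*(p - s))) <= radius_um:
                counts[k] += 1
                break
        else:
            seeds.append(p)
            counts.append(1)
    return pd.DataFrame(
        {
            "y_um": [float(s[0]) for s in seeds],
            "z_um": [float(s[1]) for s in seeds],
            "multiplicity": counts,
        }
    )


def summarize(
    results: pd.DataFrame,
    bin_width_mps: float = 0.1,
    colocate_radius_um: float = 5.0,
) -> Summary:
    """Aggregate a tracking-results table into the standard summary.

    Only unflagged transits enter the statistics.  The speed histogram uses
    ``bin_width_mps`` bins from zero; class fractions report the share of
    transits below 0.5, between 0.5 and 1, and above 1 m/s; the
    closest-approach scatter merges points within ``colocate_radius_um``
    into a single entry with a multiplicity count.
    """
    if bin_width_mps <= 0.0:
        raise ValidationError("bin width must be positive")
    empty_hist = pd.DataFrame(columns=["bin_left_mps", "bin_right_mps", "count"])
    empty_pts = pd.DataFrame(columns=["y_um", "z_um", "multiplicity"])
    if results.empty:
        logger.warning("summarize: empty results table")
        return Summary(0, 0, empty_hist, {}, {}, empty_pts)
    flags = results["flags"].fillna("").astype(str)
    good = results[flags == ""]
    n_flagged = len(results) - len(good)
    if good.empty:
        logger.warning("summarize: all %d transits flagged", len(results))
        return Summary(len(results), n_flagged, empty_hist, {}, {}, empty_pts)
    speeds = good["speed_mps"].to_numpy(dtype=float)
    edges = np.arange(0.0, speeds.max() + bin_width_mps, bin_width_mps)
    if edges[-1] <= speeds.max():
        edges = np.append(edges, edges[-1] + bin_width_mps)
    counts, edges = np.histogram(speeds, bins=edges)
    hist = pd.DataFrame(
        {"bin_left_mps": edges[:-1], "bin_right_mps": edges[1:], "count": counts}
    )
    dir_counts = good["direction"].value_counts()
    direction_fractions = {
        str(k): float(v) / len(good) for k, v in dir_counts.items()
    }
    lo, hi = VELOCITY_CLASS_EDGES
    class_fractions = {
        f"lt_{lo}": float(np.mean(speeds < lo)),
        f"{lo}_to_{hi}": float(np.mean((speeds >= lo) & (speeds <= hi))),
        f"gt_{hi}": float(np.mean(speeds > hi)),
    }
    pts = good[["y_um", "z_um"]].to_numpy(dtype=float)
    approach = _colocate(pts, colocate_radius_um)
    return Summary(
        n_total=len(results),
        n_flagged=n_flagged,
        speed_histogram=hist,
        direction_fractions=direction_fractions,
        class_fractions=class_fractions,
        approach_points=approach,
    )
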