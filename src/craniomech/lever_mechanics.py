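"""Jaw-closing mechanical advantage from 2D lever geometry.

Mechanical advantage (MA) of a jaw lever system is the in-lever length
(jaw joint to muscle insertion on the lower jaw) divided by the out-lever
length (jaw joint to bite point).  Two adductor muscle groups visible in
lateral view are modelled: the temporal group (mAMES/mAMEM/mAMEP/mPSTs)
and the quadrate group (mAMP/mPSTp); the pterygoid group is omitted as its
measurement points are hidden in lateral view.  Each insertion is a single
representative point (the region centroid when the attachment is an area).

ΔMA = quadrate MA − temporal MA summarises how differently the two groups
leverage the same bite point.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class LeverSet:
    """Lever points (mm) of one taxon's jaw system."""

    taxon_id: str
    jaw_joint: tuple[float, float]
    temporal_insertion: tuple[float, float]
    quadrate_insertion: tuple[float, float]
    anterior_bite_point: tuple[float, float]
    posterior_bite_point: tuple[float, float] | None = None

    def validate(self) -> None:
        j = np.asarray(self.jaw_joint, dtype=float)
        for name in ("temporal_insertion", "quadrate_insertion",
                     "anterior_bite_point", "posterior_bite_point"):
            p = getattr(self, name)
            if p is None:
                continue
            if np.allclose(np.asarray(p, dtype=float), j):
                raise ValueError(f"{self.taxon_id}: {name} coincides with the jaw joint")


@dataclass
class MAResult:
    taxon_id: str
    temporal_ma: float
    quadrate_ma: float
    delta_ma: float


def mechanical_advantage(joint, insertion, bite) -> float:
    """In-lever / out-lever: ||insertion-joint|| / ||bite-joint||."""
    joint = np.asarray(joint, dtype=float)
    in_lever = float(np.linalg.norm(np.asarray(insertion, dtype=float) - joint))
    out_lever = float(np.linalg.norm(np.asarray(bite, dtype=float) - joint))
    if out_lever == 0.0:
        raise ValueError("zero out-lever: bite point coincides with the jaw joint")
    return in_lever / out_lever


def delta_ma(temporal_ma: float, quadrate_ma: float) -> float:
    """Quadrate-group MA minus temporal-group MA."""
    if not (np.isfinite(temporal_ma) and np.isfinite(quadrate_ma)):
        raise ValueError("MA values must be finite")
    return float(quadrate_ma) - float(temporal_ma)


_ANTERIOR_COLUMNS = ["taxon_id", "temporal_ma", "quadrate_ma", "delta_ma"]
_POSTERIOR_COLUMNS = ["posterior_temporal_ma", "posterior_quadrate_ma",
                      "posterior_delta_ma"]


def ma_table(levers: list[LeverSet], decimals: int | None = None) -> pd.DataFrame:
    """One MA row per taxon; posterior columns appear when any set has a
    posterior bite point.  Values are raw unless ``decimals`` is given
    (presentation rounding only)."""
    seen: set[str] = set()
    any_posterior = any(lv.posterior_bite_point is not None for lv in levers)
    rows = []
    for lv in levers:
        if lv.taxon_id in seen:
            raise ValueError(f"duplicate taxon_id {lv.taxon_id!r}")
        seen.add(lv.taxon_id)
        lv.validate()
        t = mechanical_advantage(lv.jaw_joint, lv.temporal_insertion,
                                 lv.anterior_bite_point)
        q = mechanical_advantage(lv.jaw_joint, lv.quadrate_insertion,
                                 lv.anterior_bite_point)
        row = {"taxon_id": lv.taxon_id, "temporal_ma": t, "quadrate_ma": q,
               "delta_ma": delta_ma(t, q)}
        if any_posterior:
            if lv.posterior_bite_point is not None:
                pt = mechanical_advantage(lv.jaw_joint, lv.temporal_insertion,
                                          lv.posterior_bite_point)
                pq = mechanical_advantage(lv.jaw_joint, lv.quadrate_insertion,
                                          lv.posterior_bite_point)
                row.update(posterior_temporal_ma=pt, posterior_quadrate_ma=pq,
                           posterior_delta_ma=delta_ma(pt, pq))
            else:
                row.update(posterior_temporal_ma=np.nan,
                           posterior_quadrate_ma=np.nan,
                           posterior_delta_ma=np.nan)
        rows.append(row)
    columns = _ANTERIOR_COLUMNS + (_POSTERIOR_COLUMNS if any_posterior else [])
    df = pd.DataFrame(rows, columns=columns)
    if decimals is not None:
        num = df.columns.drop("taxon_id")
        df[num] = df[num].round(decimals)
    return df


# ---------------------------------------------------------------------------
# CSV I/O (taxon_id, role, x_mm, y_mm)
# ---------------------------------------------------------------------------

_ROLES = ("jaw_joint", "temporal_insertion", "quadrate_insertion",
          "anterior_bite_point", "posterior_bite_point")


def write_lever_csv(levers: list[LeverSet], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["taxon_id", "role", "x_mm", "y_mm"])
        for lv in levers:
            for role in _ROLES:
                p = getattr(lv, role)
                if p is None:
                    continue
                w.writerow([lv.taxon_id, role, f"{p[0]:.12g}", f"{p[1]:.12g}"])


def read_lever_csv(path) -> list[LeverSet]:
    points: dict[str, dict[str, tuple[float, float]]] = {}
    order: list[str] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            taxon = row["taxon_id"]
            role = row["role"]
            if role not in _ROLES:
                raise ValueError(f"unknown lever role {role!r}")
            if taxon not in points:
                points[taxon] = {}
                order.append(taxon)
            points[taxon][role] = (float(row["x_mm"]), float(row["y_mm"]))
    levers = []
    for taxon in order:
        d = points[taxon]
        missing = [r for r in _ROLES[:4] if r not in d]
        if missing:
            raise ValueError(f"{taxon}: missing lever roles {missing}")
        levers.append(LeverSet(taxon_id=taxon, jaw_joint=d["jaw_joint"],
                               temporal_insertion=d["temporal_insertion"],
                               quadrate_insertion=d["quadrate_insertion"],
                               anterior_bite_point=d["anterior_bite_point"],
                               posterior_bite_point=d.get("posterior_bite_point")))
    return levers
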