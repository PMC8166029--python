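"""Synthetic plate tables: per-embryo neutrophil counts and ROS intensities.

Neutrophil counts are Poisson (the simplest strictly-positive count model);
ROS intensities are log-normal. A candidate's true effect e in [0, 1] enters
as linear interpolation between the model and control parameters, so e is
commensurate with the recovery-rate scale: e = 1 restores the control mean,
e = 0 leaves the model mean unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["PlateSpec", "PlateTable", "generate_plate"]

MIN_EMBRYOS = 5  # at least 5 embryos examined per treatment condition


@dataclass(frozen=True)
class PlateSpec:
    """Parameters of a synthetic screening plate.

    ``candidates`` holds (name, true_effect_neutrophil, true_effect_ros)
    triples with effects in [0, 1]. Default means put the model arm well
    above control (5 vs 20 neutrophils) so recovery-rate denominators are
    far from zero; ROS log-means give a model/control intensity ratio near 2.
    """

    lambda_control: float = 5.0
    lambda_model: float = 20.0
    mu_ros_control: float = 6.9   # log-scale; exp(6.9) ~ 1000 a.u.
    mu_ros_model: float = 7.6     # exp(7.6) ~ 2000 a.u.
    sigma_ros: float = 0.2
    candidates: tuple[tuple[str, float, float], ...] = ()
    n_embryos: int = 10
    seed: int = 0

    def validate(self) -> None:
        if not self.lambda_model > self.lambda_control > 0:
            raise ValueError(
                f"require lambda_model > lambda_control > 0, got "
                f"lambda_model={self.lambda_model}, lambda_control={self.lambda_control}"
            )
        if self.n_embryos < MIN_EMBRYOS:
            raise ValueError(f"n_embryos must be >= {MIN_EMBRYOS}, got {self.n_embryos}")
        if self.sigma_ros <= 0:
            raise ValueError(f"sigma_ros must be > 0, got {self.sigma_ros}")
        names = [c[0] for c in self.candidates]
        if len(set(names)) != len(names):
            raise ValueError("candidates: names must be unique")
        for name, e_n, e_r in self.candidates:
            if name in ("control", "model"):
                raise ValueError(f"candidates: name {name!r} is reserved")
            if not (0.0 <= e_n <= 1.0 and 0.0 <= e_r <= 1.0):
                raise ValueError(
                    f"candidates: effects for {name!r} must be in [0, 1], "
                    f"got ({e_n}, {e_r})"
                )


@dataclass
class PlateTable:
    """Per-embryo measurements plus the generating ground truth."""

    table: pd.DataFrame  # columns: well, group, embryo_id, neutrophil_count, ros_intensity
    true_effects: dict[str, tuple[float, float]] = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def load(cls, path: str | Path) -> "PlateTable":
        return cls(table=pd.read_csv(path))


def candidate_lambda(lambda_model: float, lambda_control: float, effect: float) -> float:
    """Poisson mean of a candidate arm: model mean shrunk toward control by `effect`."""
    return lambda_model - effect * (lambda_model - lambda_control)


def generate_plate(spec: PlateSpec) -> PlateTable:
    """Draw a plate: control, model, then one arm per candidate."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    arms: list[tuple[str, float, float]] = [
        ("control", spec.lambda_control, spec.mu_ros_control),
        ("model", spec.lambda_model, spec.mu_ros_model),
    ]
    for name, e_n, e_r in spec.candidates:
        lam = candidate_lambda(spec.lambda_model, spec.lambda_control, e_n)
        mu = spec.mu_ros_model - e_r * (spec.mu_ros_model - spec.mu_ros_control)
        arms.append((name, lam, mu))

    rows = []
    well = 0
    for group, lam, mu in arms:
        counts = rng.poisson(lam, spec.n_embryos)
        ros = rng.lognormal(mu, spec.sigma_ros, spec.n_embryos)
        for i in range(spec.n_embryos):
            rows.append(
                {
                    "well": f"{chr(ord('A') + well // 12)}{well % 12 + 1:02d}",
                    "group": group,
                    "embryo_id": i,
                    "neutrophil_count": int(counts[i]),
                    "ros_intensity": float(np.round(ros[i], 4)),
                }
            )
            well += 1

    truth = {name: (e_n, e_r) for name, e_n, e_r in spec.candidates}
    return PlateTable(table=pd.DataFrame(rows), true_effects=truth)
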