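"""The factorial simulation sweep feeding all downstream analyses.

Each muscle is simulated at every combination of model variant, activation
level and passive MTU length.  Passive lengths are laid out in normalized
fiber-length space (so muscles of very different absolute size see the same
operating-range coverage): the span is divided into base regions (postures),
each tiled with evenly spaced deviations, and each target is converted to an
MTU length through the closed-form zero-activation inverse.  With the
39-muscle reference set, 3 variants, 5 activation levels and the default 80
length settings per muscle the sweep comprises 46,800 conditions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .muscle_curves import CurveSet
from .mtu_equilibrium import (
    ModelVariant,
    MuscleParams,
    mtu_length_for_passive_length,
    solve_equilibrium,
)
from .analysis import classify_limb

__all__ = ["SweepConfig", "build_condition_grid", "run_sweep"]

log = logging.getLogger(__name__)

DEFAULT_ACTIVATIONS = (0.0, 0.25, 0.5, 0.75, 1.0)


@dataclass(frozen=True)
class SweepConfig:
    """Factor layout of the sweep.

    ``n_base_lengths * n_deviations_per_base`` MTU lengths are generated per
    muscle; the default 4 x 20 = 80 settings reproduce the reference design's
    46,800 conditions for 39 muscles.
    """

    activation_levels: tuple = DEFAULT_ACTIVATIONS
    variants: tuple = (ModelVariant.NCNS, ModelVariant.CNS, ModelVariant.CS)
    n_base_lengths: int = 4
    n_deviations_per_base: int = 20
    passive_length_span: tuple = (0.55, 1.45)
    seed: int = 0

    def __post_init__(self) -> None:
        levels = tuple(self.activation_levels)
        if list(levels) != sorted(levels):
            raise ValueError("activation_levels must be sorted")
        if any(not 0.0 <= a <= 1.0 for a in levels):
            raise ValueError("activation_levels must lie in [0, 1]")
        if 0.0 not in levels:
            raise ValueError("activation_levels must include 0 (passive reference)")
        if self.n_base_lengths < 1 or self.n_deviations_per_base < 1:
            raise ValueError("grid counts must be positive")
        lo, hi = self.passive_length_span
        if not 0 < lo < hi:
            raise ValueError("passive_length_span must be a positive interval")

    @property
    def n_lengths(self) -> int:
        return self.n_base_lengths * self.n_deviations_per_base


def _passive_targets(config: SweepConfig) -> np.ndarray:
    """Evenly tiled passive-length targets: bases x deviations over the span."""
    lo, hi = config.passive_length_span
    edges = np.linspace(lo, hi, config.n_base_lengths + 1)
    targets = []
    for b in range(config.n_base_lengths):
        seg = np.linspace(edges[b], edges[b + 1], config.n_deviations_per_base + 1)
        targets.append((seg[:-1] + seg[1:]) / 2.0)  # deviations around the base
    return np.concatenate(targets)


def build_condition_grid(muscles, config: SweepConfig, curves: CurveSet | None = None):
    """Deterministic list of (muscle, variant, activation, mtu_length) dicts.

    MTU lengths are placed so the zero-activation fiber lengths tile
    ``passive_length_span``; targets below a pennate muscle's geometric
    floor are clipped out with a warning.
    """
    if not muscles:
        raise ValueError("muscle list must be non-empty")
    curves = curves or CurveSet()
    conditions = []
    for m in muscles:
        targets = _passive_targets(config)
        floor = np.sin(m.pennation_at_optimal)
        keep = targets > floor
        if not keep.all():
            log.warning(
                "muscle %s: %d passive targets below the pennation floor clipped",
                m.name, int((~keep).sum()),
            )
        for target in targets[keep]:
            mtu = mtu_length_for_passive_length(float(target), m, curves)
            for variant in config.variants:
                for a in config.activation_levels:
                    conditions.append(
                        {
                            "muscle": m,
                            "variant": variant,
                            "activation": float(a),
                            "mtu_length": mtu,
                            "passive_target": float(target),
                        }
                    )
    return conditions


def run_sweep(conditions, curves: CurveSet | None = None) -> pd.DataFrame:
    """Solve every condition and return the flat results table.

    Columns: muscle, group, variant, activation, mtu_length,
    passive_norm_length (the variant's own zero-activation length),
    eq_norm_length, norm_force, tendon_strain, tm_ratio, limb, converged.
    Non-converged rows are excluded (logged); more than 1% of them aborts
    the run.
    """
    curves = curves or CurveSet()
    rows = []
    for cond in conditions:
        m: MuscleParams = cond["muscle"]
        res = solve_equilibrium(
            cond["mtu_length"], cond["activation"], cond["variant"], m, curves
        )
        rows.append(
            {
                "muscle": m.name,
                "group": m.group,
                "variant": cond["variant"].value,
                "activation": cond["activation"],
                "mtu_length": cond["mtu_length"],
                "eq_norm_length": res.norm_fiber_length,
                "norm_force": res.norm_force,
                "tendon_strain": res.tendon_strain,
                "tm_ratio": m.tm_ratio,
                "converged": res.converged,
            }
        )
    table = pd.DataFrame(rows)

    n_bad = int((~table["converged"]).sum())
    if n_bad:
        log.warning("%d non-converged conditions excluded from the sweep", n_bad)
    if n_bad > 0.01 * len(table):
        raise RuntimeError(
            f"{n_bad}/{len(table)} conditions failed to converge (> 1%)"
        )

    # back-fill each variant's own passive (activation-0) reference length
    passive = (
        table[table["activation"] == 0.0]
        .set_index(["muscle", "variant", "mtu_length"])["eq_norm_length"]
    )
    table["passive_norm_length"] = [
        passive.loc[(r.muscle, r.variant, r.mtu_length)]
        for r in table.itertuples()
    ]
    table["limb"] = [
        classify_limb(x) for x in table["passive_norm_length"]
    ]
    table = table[table["converged"]].drop(columns="converged").reset_index(drop=True)
    return table
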