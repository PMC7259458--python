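"""Operating-range and force-capacity analyses over the sweep table.

Two analyses are implemented:

1. coarse binning into compliance class (T/M ratio below/above 2) and
   passive-length limb (ascending / plateau / descending) with group means
   of normalized length, force and activation-induced length change;
2. fine-grained sensitivity maps: matched model variants are compared
   condition by condition through the relative force difference
   ``%dF = 100 * (F_complex - F_simple) / F_simple`` and binned on a
   (passive length x T/M ratio) grid, reporting per bin the sample count
   and the fraction of samples whose |%dF| exceeds a threshold (10% by
   default) — the map of where model simplifications matter.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = [
    "classify_limb",
    "ncns_force",
    "shift_contribution",
    "percent_delta_force",
    "group_summaries",
    "pair_variants",
    "sensitivity_map",
    "PLATEAU_BOUNDS",
    "LOW_HIGH_TM_SPLIT",
]

log = logging.getLogger(__name__)

#: Normalized-length band treated as the force-length plateau.
PLATEAU_BOUNDS = (0.95, 1.05)
#: T/M ratio separating low- from high-compliance muscles.
LOW_HIGH_TM_SPLIT = 2.0
#: Simple-model forces at or below this are excluded from relative comparisons.
FORCE_FLOOR = 1e-6


def classify_limb(passive_norm_length: float, plateau=PLATEAU_BOUNDS) -> str:
    """Ascending ('A'), plateau ('P') or descending ('D') limb of the F-L curve."""
    if passive_norm_length <= 0:
        raise ValueError("passive_norm_length must be positive")
    lo, hi = plateau
    if passive_norm_length < lo:
        return "A"
    if passive_norm_length > hi:
        return "D"
    return "P"


def ncns_force(activation: float, active_multiplier_at_passive_length: float) -> float:
    """Rigid-tendon normalized force: activation scales the fixed-length multiplier."""
    if not 0.0 <= activation <= 1.0:
        raise ValueError("activation must lie in [0, 1]")
    if not 0.0 <= active_multiplier_at_passive_length <= 1.0:
        raise ValueError("multiplier must lie in [0, 1]")
    return activation * active_multiplier_at_passive_length


def shift_contribution(length_cs: float, length_cns: float) -> float:
    """Length change attributable to the activation-dependent shift, L_CS - L_CNS."""
    return length_cs - length_cns


def percent_delta_force(f_complex: float, f_simple: float) -> float:
    """Relative force difference between models, in percent of the simpler one."""
    if f_simple <= FORCE_FLOOR:
        raise ValueError("f_simple at or below the force floor; %dF undefined")
    return 100.0 * (f_complex - f_simple) / f_simple


def group_summaries(sweep_table: pd.DataFrame) -> pd.DataFrame:
    """Cell means over (compliance class x limb x activation x variant).

    ``mean_delta_length`` averages each record's fiber-length change from its
    own variant's passive reference.  Empty cells are simply absent.
    """
    t = sweep_table.copy()
    t["compliance_class"] = np.where(
        t["tm_ratio"] < LOW_HIGH_TM_SPLIT, "Low", "High"
    )
    t["delta_length"] = t["eq_norm_length"] - t["passive_norm_length"]
    out = (
        t.groupby(["compliance_class", "limb", "activation", "variant"])
        .agg(
            mean_norm_length=("eq_norm_length", "mean"),
            mean_norm_force=("norm_force", "mean"),
            mean_delta_length=("delta_length", "mean"),
            n=("eq_norm_length", "size"),
        )
        .reset_index()
    )
    return out


def pair_variants(
    sweep_table: pd.DataFrame,
    simple: str,
    complex: str,
    activation: float | None = None,
) -> pd.DataFrame:
    """Match records of two variants by (muscle, MTU length, activation).

    Returns one row per matched condition with both forces and lengths and
    the derived ``pct_delta_force`` (NaN where the simple model's force is
    below the floor) and ``delta_length`` columns.
    """
    cols = [
        "muscle", "mtu_length", "activation", "tm_ratio",
        "eq_norm_length", "norm_force", "passive_norm_length", "limb",
    ]
    s = sweep_table[sweep_table["variant"] == simple][cols]
    c = sweep_table[sweep_table["variant"] == complex][cols]
    merged = s.merge(
        c,
        on=["muscle", "mtu_length", "activation"],
        suffixes=("_simple", "_complex"),
        validate="one_to_one",
    )
    if activation is not None:
        merged = merged[merged["activation"] == activation].reset_index(drop=True)
    defined = merged["norm_force_simple"] > FORCE_FLOOR
    merged["pct_delta_force"] = np.where(
        defined,
        100.0
        * (merged["norm_force_complex"] - merged["norm_force_simple"])
        / merged["norm_force_simple"],
        np.nan,
    )
    merged["delta_length"] = (
        merged["eq_norm_length_complex"] - merged["eq_norm_length_simple"]
    )
    return merged


def _tm_bin_index(tm: np.ndarray) -> np.ndarray:
    """Bin index on the non-uniform T/M grid: width 0.2 below 2, 1.0 above."""
    low = np.floor(tm / 0.2).astype(int)
    high = 10 + np.floor(tm - LOW_HIGH_TM_SPLIT).astype(int)
    return np.where(tm < LOW_HIGH_TM_SPLIT, low, high)


def _tm_bin_edges(idx: np.ndarray):
    lo = np.where(idx < 10, idx * 0.2, LOW_HIGH_TM_SPLIT + (idx - 10) * 1.0)
    hi = np.where(idx < 10, (idx + 1) * 0.2, LOW_HIGH_TM_SPLIT + (idx - 9) * 1.0)
    return lo, hi


def sensitivity_map(
    sweep_table: pd.DataFrame,
    variant_pair=("NCNS", "CNS"),
    activation: float = 0.25,
    threshold_pct: float = 10.0,
    length_bin_width: float = 0.05,
) -> pd.DataFrame:
    """Binned fraction of conditions with a meaningful force change.

    Passive lengths (of the more complex model) are binned in steps of 5%
    of L0 and T/M ratios on a grid that is finer (0.2) for low-compliance
    muscles than for high-compliance ones (1.0).  Each bin reports its
    sample count and the fraction of samples with |%dF| above the
    threshold.  Conditions with an undefined %dF (simple-model force ~ 0)
    are excluded; their count is logged and stored in ``.attrs``.
    """
    simple, complex = variant_pair
    pairs = pair_variants(sweep_table, simple, complex, activation=activation)
    if pairs.empty:
        raise ValueError("no matched records for the requested pair/activation")
    n_undef = int(pairs["pct_delta_force"].isna().sum())
    if n_undef:
        log.info("%d conditions with undefined %%dF excluded from binning", n_undef)
    ok = pairs.dropna(subset=["pct_delta_force"]).copy()

    ok["length_bin"] = np.floor(
        ok["passive_norm_length_complex"] / length_bin_width
    ).astype(int)
    ok["tm_bin"] = _tm_bin_index(ok["tm_ratio_simple"].to_numpy())
    ok["exceeds"] = ok["pct_delta_force"].abs() > threshold_pct

    grouped = (
        ok.groupby(["tm_bin", "length_bin"])
        .agg(n_samples=("exceeds", "size"), frac_exceeding=("exceeds", "mean"))
        .reset_index()
    )
    tm_lo, tm_hi = _tm_bin_edges(grouped["tm_bin"].to_numpy())
    grouped["tm_lo"], grouped["tm_hi"] = tm_lo, tm_hi
    grouped["length_lo"] = grouped["length_bin"] * length_bin_width
    grouped["length_hi"] = (grouped["length_bin"] + 1) * length_bin_width
    grouped.attrs["n_excluded"] = n_undef
    grouped.attrs["variant_pair"] = (simple, complex)
    grouped.attrs["activation"] = activation
    return grouped
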