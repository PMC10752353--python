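"""Permutation placebo tests.

Falsification by deliberately breaking the pollution–productivity
pairing: the pollution block is permuted across county-years (globally
or within strata), the model is re-estimated on each permuted panel,
and the baseline estimate is located within the resulting placebo
distribution.  A genuine effect should fall in the far tail.

By default the wind-bin instrument counts travel with the pollution
variables under the permutation, so each placebo fit retains a strong
first stage while the pollution→TFP link is severed; permuting the
pollution columns alone (``move_instruments=False``) is also supported
but leaves the placebo fits weakly identified.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .paneliv import PanelIVModel
from .weather import WIND_BIN_COLUMNS

__all__ = ["PlaceboRun", "permute_panel", "placebo_distribution"]

logger = logging.getLogger(__name__)

POLLUTION_COLUMNS = (
    "ozone_annual",
    "ozone_winter",
    "ozone_nonwinter",
    "aot40",
    "sum06",
    "w126",
    "pm25",
)


@dataclasses.dataclass
class PlaceboRun:
    """A placebo distribution and the baseline's position in it."""

    mode: str
    estimates: np.ndarray
    baseline: float
    coefficient: str
    seed: int
    n_failed: int = 0

    @property
    def n_reps(self) -> int:
        return len(self.estimates)

    @property
    def tail_probability(self) -> float:
        """Two-sided empirical tail probability of the baseline, with the
        add-one permutation-test convention."""
        more_extreme = np.sum(np.abs(self.estimates) >= abs(self.baseline))
        return float((1 + more_extreme) / (1 + self.n_reps))

    def outside_range(self) -> bool:
        """Whether the baseline falls outside [min, max] of the placebo
        estimates."""
        return bool(
            self.baseline < self.estimates.min() or self.baseline > self.estimates.max()
        )

    def summary(self) -> str:
        return (
            f"placebo ({self.mode}, {self.n_reps} reps): baseline "
            f"{self.coefficient}={self.baseline:+.5f}, placebo mean "
            f"{self.estimates.mean():+.5f} sd {self.estimates.std():.5f}, "
            f"tail p={self.tail_probability:.4f}"
        )


def permute_panel(
    panel: pd.DataFrame,
    mode: str = "global",
    seed: int = 0,
    strata_cols: tuple[str, ...] = ("group", "year"),
    move_instruments: bool = True,
    target: str = "pollution",
    outcome_col: str = "log_tfp",
) -> pd.DataFrame:
    """Break the pollution–productivity pairing by permuting rows.

    ``target="pollution"`` (default) permutes the pollution block —
    exposure columns plus, unless ``move_instruments`` is False, the
    wind-bin counts; ``target="outcome"`` permutes the outcome column
    instead, leaving every regressor aligned with its row (the variant
    whose placebo distribution matches the null sampling distribution,
    since the outcome carries little row-structured signal besides its
    fixed effects).

    ``mode="global"`` permutes over all rows; ``mode="stratified"``
    permutes within each cell of ``strata_cols`` (regions × years by
    default; use ``("county",)`` to preserve the county fixed-effect
    alignment), leaving size-1 strata unpermuted (logged).  The
    permutation is a bijection: every permuted column is a rearrangement
    of the original.
    """
    if mode not in ("global", "stratified"):
        raise ValueError(f"unknown placebo mode {mode!r}")
    if target == "pollution":
        cols = [c for c in POLLUTION_COLUMNS if c in panel.columns]
        if move_instruments:
            cols += [c for c in WIND_BIN_COLUMNS if c in panel.columns]
    elif target == "outcome":
        cols = [outcome_col]
    else:
        raise ValueError(f"unknown placebo target {target!r}")
    if not set(cols) <= set(panel.columns):
        raise ValueError("panel lacks the columns to permute")
    if not cols:
        raise ValueError("panel has no pollution columns to permute")
    rng = np.random.default_rng(seed)
    n = len(panel)
    if mode == "global":
        perm = rng.permutation(n)
    else:
        missing = [c for c in strata_cols if c not in panel.columns]
        if missing:
            raise KeyError(f"strata columns missing from panel: {missing}")
        perm = np.arange(n)
        codes = pd.MultiIndex.from_frame(panel[list(strata_cols)]).factorize()[0]
        n_single = 0
        for code in np.unique(codes):
            idx = np.flatnonzero(codes == code)
            if len(idx) == 1:
                n_single += 1
                continue
            perm[idx] = idx[rng.permutation(len(idx))]
        if n_single:
            logger.info("%d singleton strata left unpermuted", n_single)
    out = panel.copy()
    out[cols] = panel[cols].to_numpy()[perm]
    return out


def placebo_distribution(
    panel: pd.DataFrame,
    n_reps: int = 1000,
    seed: int = 0,
    mode: str = "global",
    method: str = "2sls",
    coefficient: str = "ozone_annual",
    ozone: str = "annual",
    strata_cols: tuple[str, ...] = ("group", "year"),
    move_instruments: bool = True,
    target: str = "pollution",
    max_failed_frac: float = 0.05,
) -> PlaceboRun:
    """Placebo distribution of one coefficient over permuted panels.

    Fits the chosen estimator on the observed panel (the baseline) and
    on ``n_reps`` permuted panels; per-replicate seeds are drawn from a
    generator seeded with ``seed``, so the full estimate vector is
    reproducible.  More than ``max_failed_frac`` failed fits aborts.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be positive")
    baseline = PanelIVModel.from_panel(panel, ozone=ozone).fit(method)
    base_est = float(baseline.params[coefficient])

    root = np.random.default_rng(seed)
    rep_seeds = root.integers(0, 2**31 - 1, size=n_reps)
    estimates, n_failed = [], 0
    for rep_seed in rep_seeds:
        permuted = permute_panel(
            panel, mode=mode, seed=int(rep_seed),
            strata_cols=strata_cols, move_instruments=move_instruments,
            target=target,
        )
        try:
            res = PanelIVModel.from_panel(permuted, ozone=ozone).fit(method)
            estimates.append(float(res.params[coefficient]))
        except (np.linalg.LinAlgError, ValueError) as exc:  # pragma: no cover
            n_failed += 1
            logger.warning("placebo fit failed (seed %d): %s", rep_seed, exc)
    if n_failed > max_failed_frac * n_reps:
        raise RuntimeError(f"{n_failed}/{n_reps} placebo fits failed")
    return PlaceboRun(
        mode=mode,
        estimates=np.asarray(estimates),
        baseline=base_est,
        coefficient=coefficient,
        seed=seed,
        n_failed=n_failed,
    )
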