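"""Probabilistic and one-way sensitivity analysis.

The PSA propagates parameter uncertainty by Monte Carlo: every uncertain
parameter is drawn from its moment-matched distribution, the full
pipeline (tree -> costs -> DALYs) is evaluated, and 95% credible
intervals are read off the empirical 2.5th/97.5th percentiles (linear
interpolation between order statistics).  Countries in a region are
sampled independently and summed within each draw before quantiles are
taken — quantiles are not additive, so region intervals must come from
the joint draws, never from summing country intervals.

The one-way (tornado) analysis re-runs the deterministic base case with
one parameter at its lower and upper plausible bound while all others
stay at their point estimates, and ranks parameters by output swing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .parameters import (
    UNCERTAIN_FIELDS,
    CountryParameters,
    base_values,
    perturbed_values,
    sample_values_batch,
)
from .pipeline import flatten, run_values
from .ptsd_scenario import PtsdSpec, base_ptsd_values, sample_ptsd_values

__all__ = ["PsaResult", "TornadoEntry", "run_psa", "credible_interval",
           "one_way_sa", "plot_tornado"]

DEFAULT_N_DRAWS = 1_000


@dataclass(frozen=True)
class PsaResult:
    """Monte Carlo draws with base-case point estimates and interval level."""

    n_draws: int
    seed: int
    level: float
    point: dict[str, float]
    draws: pd.DataFrame  # one row per draw, one column per quantity

    def cri(self, quantity: str) -> tuple[float, float]:
        return credible_interval(self.draws[quantity].to_numpy(), self.level)

    def summary(self) -> pd.DataFrame:
        """Point estimate with credible interval per quantity."""
        rows = []
        for q in self.draws.columns:
            lo, hi = self.cri(q)
            rows.append({"quantity": q, "point": self.point[q],
                         "mean": float(self.draws[q].mean()),
                         "cri_low": lo, "cri_high": hi})
        return pd.DataFrame(rows).set_index("quantity")


def credible_interval(draws: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Central credible interval from empirical quantiles.

    Uses linear interpolation between order statistics; ``level=0``
    degenerates to (median, median).
    """
    draws = np.asarray(draws, dtype=float)
    if draws.size == 0:
        raise ValueError("need at least one draw")
    if not 0.0 <= level < 1.0:
        raise ValueError("level must lie in [0, 1)")
    lo, hi = np.quantile(draws, [(1.0 - level) / 2.0, (1.0 + level) / 2.0])
    return float(lo), float(hi)


def _as_country_list(params) -> list[CountryParameters]:
    if isinstance(params, CountryParameters):
        return [params]
    return list(params)


def run_psa(params: CountryParameters | Sequence[CountryParameters],
            n: int = DEFAULT_N_DRAWS,
            seed: int | None = None,
            level: float = 0.95,
            scenario: PtsdSpec | None = None,
            **pipeline_kwargs) -> PsaResult:
    """Monte Carlo PSA over one country or a region (list of countries).

    With a region, each draw samples every country independently and sums
    the additive outputs.  The same seed always reproduces the same draw
    matrix bit for bit.
    """
    countries = _as_country_list(params)
    if not countries:
        raise ValueError("need at least one country")
    if n < 2:
        raise ValueError("need at least 2 draws")
    if seed is None:
        raise ValueError("a seed is required for reproducibility")

    base_ptsd = base_ptsd_values(scenario) if scenario is not None else None
    point = _sum_rows(
        flatten(run_values(base_values(cp), ptsd=base_ptsd, **pipeline_kwargs))
        for cp in countries
    )

    rng = np.random.default_rng(seed)
    per_country = [sample_values_batch(cp, rng, n) for cp in countries]
    ptsd_draws = ([sample_ptsd_values(scenario, rng) for _ in range(n)]
                  if scenario is not None else [None] * n)
    rows = [
        _sum_rows(
            flatten(run_values(pvs[i], ptsd=ptsd_draws[i], **pipeline_kwargs))
            for pvs in per_country
        )
        for i in range(n)
    ]
    draws = pd.DataFrame(rows)
    return PsaResult(n_draws=n, seed=seed, level=level, point=point, draws=draws)


def _sum_rows(rows) -> dict[str, float]:
    total: dict[str, float] = {}
    for row in rows:
        for k, v in row.items():
            total[k] = total.get(k, 0.0) + v
    return total


# ---------------------------------------------------------------------------
# One-way sensitivity analysis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    output_at_low: float
    output_at_high: float
    base_output: float

    @property
    def swing(self) -> float:
        return abs(self.output_at_high - self.output_at_low)


def one_way_sa(cp: CountryParameters,
               parameters: Sequence[str] | None = None,
               output: str = "dalys",
               scenario: PtsdSpec | None = None,
               **pipeline_kwargs) -> list[TornadoEntry]:
    """Tornado analysis: pipeline output at each parameter's bounds.

    ``output`` names any additive pipeline quantity (e.g. ``dalys``,
    ``total_cost``, ``deaths``).  Entries come back sorted by descending
    swing.  Demographic shares are excluded: moving a single share needs a
    renormalization convention and is better explored through the PSA.
    """
    names = list(parameters) if parameters is not None else [
        n for n, _ in UNCERTAIN_FIELDS
    ]
    known = {n for n, _ in UNCERTAIN_FIELDS}
    ptsd = base_ptsd_values(scenario) if scenario is not None else None

    def evaluate(**overrides) -> float:
        pv = perturbed_values(cp, **overrides)
        return flatten(run_values(pv, ptsd=ptsd, **pipeline_kwargs))[output]

    base = evaluate()
    entries = []
    for name in names:
        if name not in known:
            warnings.warn(f"skipping unknown or unbounded parameter {name!r}",
                          stacklevel=2)
            continue
        p = getattr(cp, name)
        entries.append(TornadoEntry(
            parameter=name,
            output_at_low=evaluate(**{name: p.low}),
            output_at_high=evaluate(**{name: p.high}),
            base_output=base,
        ))
    entries.sort(key=lambda e: e.swing, reverse=True)
    return entries


def tornado_to_dataframe(entries: Sequence[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "parameter": [e.parameter for e in entries],
            "output_at_low": [e.output_at_low for e in entries],
            "output_at_high": [e.output_at_high for e in entries],
            "base_output": [e.base_output for e in entries],
            "swing": [e.swing for e in entries],
        }
    )


def plot_tornado(entries: Sequence[TornadoEntry], path=None, title=None,
                 max_bars: int = 15):
    """Horizontal-bar tornado diagram of the largest swings."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    shown = list(entries)[:max_bars][::-1]
    fig, ax = plt.subplots(figsize=(8, 0.4 * len(shown) + 1.5))
    for i, e in enumerate(shown):
        lo, hi = sorted((e.output_at_low, e.output_at_high))
        ax.barh(i, hi - lo, left=lo, color="#4878d0", height=0.6)
    ax.axvline(shown[0].base_output if shown else 0.0, color="k", lw=1)
    ax.set_yticks(range(len(shown)))
    ax.set_yticklabels([e.parameter for e in shown])
    ax.set_xlabel("output")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig
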