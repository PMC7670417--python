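"""Multi-model ensemble anomaly and spread maps.

Future-vs-historical change for an indicator is summarized across an
ensemble of climate-model runs by two cellwise maps: the ensemble-mean
anomaly (absolute, or percent of the historical reference) and the relative
standard deviation (RSD), ``100 * s / |mean|`` with the sample (n-1)
standard deviation across members.  Percent quantities blow up where the
denominator is near zero (deserts, for precipitation indicators), so both
are masked below a configurable epsilon.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .indicators import IndicatorField


@dataclass
class EnsembleStack:
    """Per-member maps of one indicator/period plus the historical reference."""

    members: list
    reference: IndicatorField

    def __post_init__(self):
        if not self.members:
            raise ValueError("ensemble stack needs at least one member")
        shape = self.reference.values.shape
        code = self.reference.bio_code
        for m in self.members:
            if m.values.shape != shape:
                raise ValueError("grid mismatch between ensemble members and reference")
            if m.bio_code != code:
                raise ValueError("ensemble members mix indicator codes")

    @property
    def n_members(self) -> int:
        return len(self.members)

    def member_array(self) -> np.ndarray:
        return np.stack([m.values for m in self.members])


def _epsilon_for(reference: np.ndarray, epsilon: float | None) -> float:
    """Default near-zero guard: 1e-6 of the field's largest finite magnitude."""
    if epsilon is not None:
        return epsilon
    finite = np.abs(reference[np.isfinite(reference)])
    scale = finite.max() if finite.size else 1.0
    return 1e-6 * max(scale, 1e-30)


def ensemble_anomaly(stack: EnsembleStack, mode: str = "percent",
                     epsilon: float | None = None) -> IndicatorField:
    """Cellwise ensemble-mean change relative to the historical reference.

    ``mode='absolute'`` returns ``mean(members) - reference`` in the
    indicator's own units; ``mode='percent'`` divides by ``|reference|`` and
    multiplies by 100, masking cells where ``|reference|`` is below the
    epsilon guard.
    """
    if mode not in ("percent", "absolute"):
        raise ValueError("mode must be 'percent' or 'absolute'")
    ref = stack.reference.values
    mean = stack.member_array().mean(axis=0)
    diff = mean - ref
    if mode == "absolute":
        values, units = diff, stack.reference.units
    else:
        eps = _epsilon_for(ref, epsilon)
        with np.errstate(divide="ignore", invalid="ignore"):
            values = 100.0 * diff / np.abs(ref)
        values = np.where(np.abs(ref) < eps, np.nan, values)
        units = "%"
    member0 = stack.members[0]
    return IndicatorField(
        bio_code=stack.reference.bio_code, values=values, units=units,
        period=member0.period, lat=stack.reference.lat, lon=stack.reference.lon,
        attrs={"long_name": f"ensemble {mode} anomaly, {stack.reference.long_name}",
               "n_members": stack.n_members},
    )


def ensemble_rsd(stack: EnsembleStack, epsilon: float | None = None) -> IndicatorField:
    """Cellwise relative standard deviation (%) across ensemble members.

    Uses the sample (n-1) standard deviation; cells whose ensemble-mean
    magnitude falls below the epsilon guard are masked.
    """
    if stack.n_members < 2:
        raise ValueError("RSD needs at least 2 ensemble members")
    arr = stack.member_array()
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1)
    eps = _epsilon_for(mean, epsilon)
    with np.errstate(divide="ignore", invalid="ignore"):
        values = 100.0 * sd / np.abs(mean)
    values = np.where(np.abs(mean) < eps, np.nan, values)
    member0 = stack.members[0]
    return IndicatorField(
        bio_code=stack.reference.bio_code, values=values, units="%",
        period=member0.period, lat=stack.reference.lat, lon=stack.reference.lon,
        attrs={"long_name": f"ensemble RSD, {stack.reference.long_name}",
               "n_members": stack.n_members, "epsilon": eps},
    )
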