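"""Percent-yield quantification from qRT-PCR threshold cycles.

Pulldown yield of a transcript is quantified by the delta-Ct method with a
per-primer amplification efficiency epsilon (fractional gain per cycle, so a
perfect doubling is epsilon = 1):

    yield% = 100 * (1 + eps) ** dCt,      dCt = Ct_input_corr - Ct_RIP_corr

The input aliquot is a fraction of the lysate (20% by default), so its raw Ct
is corrected down by log_{1+eps}(1 / input_fraction) cycles to the
full-lysate equivalent before the difference is taken. Measurement
uncertainty is propagated to first order: variances add for differences,
relative variances add for products and quotients, and a general function f
contributes sigma_f = sigma_x * |f'(x)|.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np
import pandas as pd

from .errors import ParameterError, ValidationError

logger = logging.getLogger(__name__)

MIN_PRIMER_EFFICIENCY = 0.90  # primer pairs below this average are flagged


@dataclass
class PrimerPair:
    target: str
    efficiency: float  # per-cycle amplification efficiency in [0, 1]
    efficiency_sd: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.efficiency <= 1:
            raise ParameterError(
                f"efficiency for {self.target} must be in [0, 1], got {self.efficiency}"
            )
        if self.efficiency_sd < 0:
            raise ParameterError("efficiency_sd must be >= 0")

    @property
    def flagged_low_efficiency(self) -> bool:
        return self.efficiency < MIN_PRIMER_EFFICIENCY


@dataclass
class CtMeasurement:
    sample: Literal["input", "RIP"]
    target: str
    ct_replicates: list[float]
    input_fraction: float = 0.2
    ct_offset: float = 0.0  # extra per-sample correction (e.g. elution volume)

    def __post_init__(self) -> None:
        if self.sample not in ("input", "RIP"):
            raise ValidationError(f"sample must be 'input' or 'RIP', got {self.sample!r}")
        if not self.ct_replicates:
            raise ValidationError("need at least one Ct replicate")
        if any(ct <= 0 for ct in self.ct_replicates):
            raise ValidationError("Ct values must be positive")
        if not 0 < self.input_fraction <= 1:
            raise ParameterError(
                f"input_fraction must be in (0, 1], got {self.input_fraction}"
            )


@dataclass
class YieldResult:
    target: str
    yield_percent: float
    yield_sd: float
    delta_ct: float = 0.0
    delta_ct_sd: float = 0.0
    fold_vs_reference: float | None = None
    fold_sd: float | None = None
    flagged_low_efficiency: bool = False


def corrected_ct(m: CtMeasurement, pair: PrimerPair) -> tuple[float, float]:
    """Volume-corrected mean Ct and its replicate standard deviation (n-1).

    Input samples are corrected down by log_{1+eps}(1/input_fraction) cycles;
    pulldown (RIP) samples are used as measured. A single replicate has sd 0.
    """
    if pair.efficiency <= 0:
        raise ParameterError("efficiency must be > 0 to correct Ct values")
    reps = np.asarray(m.ct_replicates, dtype=float)
    mean = float(reps.mean())
    sd = float(reps.std(ddof=1)) if reps.size > 1 else 0.0
    ct = mean + m.ct_offset
    if m.sample == "input":
        ct -= math.log(1.0 / m.input_fraction, 1.0 + pair.efficiency)
    return ct, sd


def propagate_difference(
    a: float, sigma_a: float, b: float, sigma_b: float
) -> tuple[float, float]:
    """D = A - B with sigma_D = sqrt(sigma_A^2 + sigma_B^2)."""
    if sigma_a < 0 or sigma_b < 0:
        raise ParameterError("standard deviations must be >= 0")
    return a - b, math.hypot(sigma_a, sigma_b)


def propagate_product(
    a: float,
    sigma_a: float,
    b: float,
    sigma_b: float,
    op: Literal["multiply", "divide"] = "multiply",
) -> tuple[float, float]:
    """P = A*B or A/B with sigma_P = |P| * sqrt((sA/A)^2 + (sB/B)^2)."""
    if a == 0 or b == 0:
        raise ParameterError("relative error undefined for a zero-valued operand")
    if sigma_a < 0 or sigma_b < 0:
        raise ParameterError("standard deviations must be >= 0")
    p = a * b if op == "multiply" else a / b
    return p, abs(p) * math.hypot(sigma_a / a, sigma_b / b)


def propagate_function(
    x: float,
    sigma_x: float,
    f: Callable[[float], float],
    fprime: Callable[[float], float] | None = None,
) -> tuple[float, float]:
    """sigma_f = sigma_x * |f'(x)|, with f' by central difference if not given."""
    if sigma_x < 0:
        raise ParameterError("sigma_x must be >= 0")
    if fprime is not None:
        deriv = fprime(x)
    else:
        h = 1e-6 * max(abs(x), 1.0)
        deriv = (f(x + h) - f(x - h)) / (2 * h)
    return f(x), sigma_x * abs(deriv)


def percent_yield(
    ct_input_corr: float,
    ct_input_sd: float,
    ct_rip_corr: float,
    ct_rip_sd: float,
    pair: PrimerPair,
) -> YieldResult:
    """Yield% = 100 * (1+eps)^dCt with first-order uncertainty.

    sigma_yield = sigma_dCt * yield * ln(1+eps), the derivative rule applied
    to the exponential amplification law.
    """
    delta_ct, delta_sd = propagate_difference(
        ct_input_corr, ct_input_sd, ct_rip_corr, ct_rip_sd
    )
    base = 1.0 + pair.efficiency
    y = 100.0 * base**delta_ct
    y_sd = delta_sd * y * math.log(base)
    return YieldResult(
        target=pair.target,
        yield_percent=y,
        yield_sd=y_sd,
        delta_ct=delta_ct,
        delta_ct_sd=delta_sd,
        flagged_low_efficiency=pair.flagged_low_efficiency,
    )


def fold_enrichment_vs_reference(
    target: YieldResult, reference: YieldResult
) -> tuple[float, float]:
    """Yield ratio of a target transcript over a reference (e.g. GAPDH)."""
    if reference.yield_percent == 0:
        raise ParameterError("reference yield is zero; fold enrichment undefined")
    if target.yield_percent == 0:
        return 0.0, 0.0
    return propagate_product(
        target.yield_percent,
        target.yield_sd,
        reference.yield_percent,
        reference.yield_sd,
        op="divide",
    )


def yields_from_plate(
    measurements: list[CtMeasurement],
    pairs: dict[str, PrimerPair],
    reference_target: str | None = None,
) -> pd.DataFrame:
    """Per-target percent yields (and fold vs a reference gene) from a plate.

    ``measurements`` must contain exactly one input and one RIP measurement
    per target; targets with a flagged (<90%) primer efficiency are computed
    but marked, never silently dropped.
    """
    by_key: dict[tuple[str, str], CtMeasurement] = {}
    for m in measurements:
        key = (m.target, m.sample)
        if key in by_key:
            raise ValidationError(f"duplicate measurement for {key}")
        by_key[key] = m

    results: dict[str, YieldResult] = {}
    for target, pair in pairs.items():
        try:
            m_in = by_key[(target, "input")]
            m_rip = by_key[(target, "RIP")]
        except KeyError as exc:
            raise ValidationError(f"missing input/RIP measurement for {target}") from exc
        ct_in, sd_in = corrected_ct(m_in, pair)
        ct_rip, sd_rip = corrected_ct(m_rip, pair)
        # the yield is computed from the replicate mean, so its Ct
        # uncertainty is the standard error of that mean
        sem_in = sd_in / math.sqrt(len(m_in.ct_replicates))
        sem_rip = sd_rip / math.sqrt(len(m_rip.ct_replicates))
        results[target] = percent_yield(ct_in, sem_in, ct_rip, sem_rip, pair)

    if reference_target is not None:
        ref = results[reference_target]
        for target, res in results.items():
            if target == reference_target:
                continue
            res.fold_vs_reference, res.fold_sd = fold_enrichment_vs_reference(res, ref)

    rows = [
        {
            "target": r.target,
            "yield_percent": r.yield_percent,
            "yield_sd": r.yield_sd,
            "delta_ct": r.delta_ct,
            "delta_ct_sd": r.delta_ct_sd,
            "fold_vs_reference": r.fold_vs_reference,
            "fold_sd": r.fold_sd,
            "flagged_low_efficiency": r.flagged_low_efficiency,
        }
        for r in sorted(results.values(), key=lambda r: r.target)
    ]
    return pd.DataFrame(rows)


def read_ct_table(path, sep: str = "\t") -> tuple[list[CtMeasurement], dict[str, PrimerPair]]:
    """Read a long-format Ct table: sample, target, ct (one row per replicate).

    Optional columns: efficiency, efficiency_sd, input_fraction. Efficiency
    must be constant within a target.
    """
    df = pd.read_csv(path, sep=sep, comment="#")
    required = {"sample", "target", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"Ct table lacks column(s): {sorted(missing)}")
    measurements = []
    pairs: dict[str, PrimerPair] = {}
    for (target, sample), grp in df.groupby(["target", "sample"], sort=True):
        frac = float(grp["input_fraction"].iloc[0]) if "input_fraction" in grp else 0.2
        measurements.append(
            CtMeasurement(
                sample=str(sample),
                target=str(target),
                ct_replicates=[float(v) for v in grp["ct"]],
                input_fraction=frac,
            )
        )
        eff = float(grp["efficiency"].iloc[0]) if "efficiency" in grp else 1.0
        eff_sd = float(grp["efficiency_sd"].iloc[0]) if "efficiency_sd" in grp else 0.0
        pairs.setdefault(str(target), PrimerPair(str(target), eff, eff_sd))
    return measurements, pairs
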