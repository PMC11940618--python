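"""Synthetic plate-format viability data with known ground truth.

Emulates the screening design used for renal proximal tubule cell panels:
an 8-point concentration series (0, 0.3, 1, 3, 10, 30, 100, 300 µM, with 0
denoting vehicle wells), replicate wells per concentration, and a raw
luminescence readout proportional to the number of viable cells.  The truth
is a monotone-decreasing logistic viability curve; well noise is
multiplicative log-normal with a specified coefficient of variation, which
matches the positive, heteroscedastic character of ATP-luminescence signals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Default treatment concentrations in µM; 0 denotes the vehicle control.
DEFAULT_CONCENTRATIONS: tuple[float, ...] = (0.0, 0.3, 1.0, 3.0, 10.0, 30.0, 100.0, 300.0)

#: Arbitrary expected vehicle-well luminescence.  Only ratios to vehicle
#: matter downstream, so the scale is a free choice.
VEHICLE_SIGNAL = 1.0e6


@dataclass(frozen=True)
class TruthParams:
    """Ground-truth logistic curve and noise model for one simulated plate.

    Attributes
    ----------
    top : float
        Viability (% of vehicle) asymptote at zero concentration.
    bottom : float
        Viability asymptote at infinite concentration; 0 ≤ bottom ≤ top.
    ec50_true : float
        Curve midpoint in µM (> 0).
    hill : float
        Hill slope (> 0); larger is steeper.
    noise_cv : float
        Coefficient of variation of the multiplicative well noise (≥ 0).
    n_replicates : int
        Wells per concentration (≥ 1).
    concentrations : tuple of float
        Strictly increasing µM values; a leading 0 denotes vehicle wells.
    seed : int
        Seed for the per-dataset random generator.
    """

    top: float = 100.0
    bottom: float = 0.0
    ec50_true: float = 10.0
    hill: float = 1.0
    noise_cv: float = 0.1
    n_replicates: int = 3
    concentrations: tuple[float, ...] = field(default=DEFAULT_CONCENTRATIONS)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.bottom <= self.top:
            raise ValueError(f"need 0 <= bottom <= top, got bottom={self.bottom}, top={self.top}")
        if self.hill <= 0:
            raise ValueError(f"hill must be > 0, got {self.hill}")
        if self.ec50_true <= 0:
            raise ValueError(f"ec50_true must be > 0, got {self.ec50_true}")
        if self.noise_cv < 0:
            raise ValueError(f"noise_cv must be >= 0, got {self.noise_cv}")
        if self.n_replicates < 1:
            raise ValueError(f"n_replicates must be >= 1, got {self.n_replicates}")
        conc = tuple(float(c) for c in self.concentrations)
        if len(conc) == 0:
            raise ValueError("concentrations must be non-empty")
        if any(c < 0 for c in conc):
            raise ValueError("concentrations must be non-negative")
        if any(b <= a for a, b in zip(conc, conc[1:])):
            raise ValueError("concentrations must be strictly increasing")
        object.__setattr__(self, "concentrations", conc)


def logistic_viability(
    c: np.ndarray | float,
    top: float,
    bottom: float,
    ec50: float,
    hill: float,
) -> np.ndarray | float:
    """Evaluate the decreasing logistic v(c) = bottom + (top−bottom)/(1+(c/ec50)^hill).

    Vehicle (c = 0) evaluates to ``top`` exactly.
    """
    c = np.asarray(c, dtype=float)
    ratio = np.zeros_like(c)
    nz = c > 0
    ratio[nz] = (c[nz] / ec50) ** hill
    out = bottom + (top - bottom) / (1.0 + ratio)
    return out if out.ndim else float(out)


def generate_plate_dataset(
    params: TruthParams,
    cell_source: str = "SIM",
    drug: str = "simdrug",
) -> pd.DataFrame:
    """Simulate raw viability wells for one (cell source, drug) series.

    Returns a long-format frame with columns ``cell_source``, ``drug``,
    ``concentration_uM``, ``replicate``, ``signal``.  The expected signal is
    ``VEHICLE_SIGNAL × v(c)/top`` so vehicle wells average the vehicle scale;
    the multiplicative noise factor is log-normal with unit mean and the
    requested CV.  The same ``TruthParams`` (including seed) always produce a
    byte-identical frame.
    """
    rng = np.random.default_rng(params.seed)
    conc = np.repeat(params.concentrations, params.n_replicates)
    replicate = np.tile(np.arange(1, params.n_replicates + 1), len(params.concentrations))
    truth = logistic_viability(conc, params.top, params.bottom, params.ec50_true, params.hill)
    expected = VEHICLE_SIGNAL * np.asarray(truth) / params.top

    if params.noise_cv > 0:
        # log-normal with E[factor] = 1 and SD/mean = noise_cv
        sigma = np.sqrt(np.log1p(params.noise_cv**2))
        factor = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=conc.size)
    else:
        factor = np.ones(conc.size)

    return pd.DataFrame(
        {
            "cell_source": cell_source,
            "drug": drug,
            "concentration_uM": conc,
            "replicate": replicate,
            "signal": expected * factor,
        }
    )


def generate_screen_dataset(
    truths: dict[tuple[str, str], TruthParams],
) -> pd.DataFrame:
    """Concatenate simulated series for a {(cell_source, drug): truth} design."""
    frames = [
        generate_plate_dataset(p, cell_source=cs, drug=dr)
        for (cs, dr), p in sorted(truths.items())
    ]
    if not frames:
        raise ValueError("empty design")
    return pd.concat(frames, ignore_index=True)
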