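"""Statistical total correlation spectroscopy (STOCSY).

Correlates one driver resonance's intensities with every spectral feature
across samples.  Resonances of the same molecule share the concentration
as a latent variable, so they light up with r near 1; the covariance trace
is kept for intensity-proportional display, the usual STOCSY rendering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectra import SpectrumSet


@dataclass
class StocsyTrace:
    driver_ppm: float          # snapped to the grid
    driver_index: int
    ppm: np.ndarray
    correlation: np.ndarray
    covariance: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"ppm": self.ppm, "r": self.correlation,
                             "cov": self.covariance})

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def correlation_at(self, ppm: float) -> float:
        return float(self.correlation[int(np.argmin(np.abs(self.ppm - ppm)))])


def stocsy(spectra: SpectrumSet, driver_ppm: float) -> StocsyTrace:
    """Pearson correlation and covariance of the driver feature with every
    feature, across samples; the driver is snapped to the nearest grid
    point."""
    if spectra.n_samples < 3:
        raise ValueError("need at least 3 samples")
    j = spectra.nearest_feature(driver_ppm)
    x = spectra.intensities
    d = x[:, j]
    if d.std() == 0:
        raise ValueError("constant driver feature")
    xc = x - x.mean(axis=0)
    dc = d - d.mean()
    n = x.shape[0]
    cov = (xc.T @ dc) / (n - 1)
    sd = x.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = cov / (sd * d.std(ddof=1))
    r[sd == 0] = np.nan
    r[j] = 1.0
    return StocsyTrace(float(spectra.ppm[j]), j, spectra.ppm.copy(), r, cov)
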