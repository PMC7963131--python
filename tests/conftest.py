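"""Shared fixtures: coarse-grid template sets and small synthetic cohorts.

The test templates use short T2 (broad lines) so that each multiplet spans
10+ grid points on a coarse 4096-point axis; the package defaults target
the full 32k-point axis where the narrow serum linewidths achieve the
same.
"""

from __future__ import annotations

import numpy as np
import pytest

from nmrmwas import CohortSpec, GridSpec, SpectrumSet
from nmrmwas.synthetic import generate_cohort
from nmrmwas.templates import MetaboliteTemplate, Multiplet


TEST_GRID = GridSpec(ppm_min=0.5, ppm_max=9.5, n_points=4096)
# grid step ~0.0022 ppm; T2 = 0.02 s -> FWHM ~15.9 Hz ~ 0.027 ppm ~ 12 points


def wide_singlet(name, ppm, t2=0.02, **kw):
    return MetaboliteTemplate(name, peaks=(Multiplet(ppm, (0.0,), (1.0,), t2),), **kw)


def wide_templates() -> list[MetaboliteTemplate]:
    return [
        MetaboliteTemplate(
            "metab_a",
            peaks=(Multiplet(1.50, (0.0,), (1.0,), 0.02),
                   Multiplet(3.50, (0.0,), (1.0,), 0.02)),
            effect_on_cac=0.30,
            effect_on_imt=0.02,
            log_hazard_ratio=0.30,
            kegg_id="C00001",
        ),
        wide_singlet("metab_b", 2.50, effect_on_cac=-0.20, kegg_id="C00003"),
        wide_singlet("metab_c", 5.233, kegg_id="C00005"),
        wide_singlet("metab_d", 7.00, kegg_id="C00007"),
    ]


@pytest.fixture(scope="session")
def grid():
    return TEST_GRID


@pytest.fixture(scope="session")
def templates():
    return wide_templates()


@pytest.fixture(scope="session")
def planted_cohort(grid, templates):
    """n=600 cohort with a strong planted CAC effect, no zero inflation."""
    spec = CohortSpec("DISC", n_samples=600, cac_zero_probability=0.0,
                      baseline_amplitude=0.3, noise_sd=0.01, seed=11)
    return generate_cohort(spec, templates, "standard1d", grid)


@pytest.fixture(scope="session")
def null_cohort(grid):
    """Cohort whose metabolites carry no phenotype effects."""
    tmpl = [wide_singlet("null_a", 1.5), wide_singlet("null_b", 3.5),
            wide_singlet("null_c", 6.0)]
    spec = CohortSpec("NULL", n_samples=400, cac_zero_probability=0.0,
                      baseline_amplitude=0.3, noise_sd=0.01, seed=23)
    return generate_cohort(spec, tmpl, "standard1d", grid)


def latent_block_spectra(blocks, n_samples=200, noise=0.01, seed=0,
                         assay="standard1d"):
    """SpectrumSet whose features are built block-wise from latent
    variables: ``blocks`` is a list of (size, latent_id); features in a
    block equal that latent plus independent noise; latent_id None means
    pure noise."""
    rng = np.random.default_rng(seed)
    n_latent = max((b for _, b in blocks if b is not None), default=-1) + 1
    latents = rng.standard_normal((n_samples, max(n_latent, 1)))
    cols = []
    for size, lid in blocks:
        for _ in range(size):
            if lid is None:
                cols.append(rng.standard_normal(n_samples))
            else:
                cols.append(latents[:, lid] + noise * rng.standard_normal(n_samples))
    x = np.column_stack(cols)
    m = x.shape[1]
    ppm = np.linspace(0.5, 0.5 + 0.01 * m, m)
    return SpectrumSet(x, ppm, assay, [f"s{i}" for i in range(n_samples)])
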