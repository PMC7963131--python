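"""SpectrumSet: samples x ppm-indexed intensity matrix with metadata.

The ppm axis is stored ascending internally; the TSV writer emits the axis
descending, the usual NMR display convention, and the reader accepts either
order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_ASSAYS = ("standard1d", "cpmg")


@dataclass
class SpectrumSet:
    """Aligned spectral matrix for one assay.

    Attributes
    ----------
    intensities : ndarray, shape (n_samples, n_features)
    ppm : ndarray, shape (n_features,), strictly increasing
    assay : {"standard1d", "cpmg"}
    sample_ids, cohort, phase : per-sample labels
    """

    intensities: np.ndarray
    ppm: np.ndarray
    assay: str
    sample_ids: list[str]
    cohort: list[str] = field(default_factory=list)
    phase: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.ppm = np.asarray(self.ppm, dtype=float)
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be 2-D (samples x features)")
        n, m = self.intensities.shape
        if self.ppm.shape != (m,):
            raise ValueError("ppm axis length must equal feature count")
        if m > 1 and not np.all(np.diff(self.ppm) > 0):
            raise ValueError("ppm axis must be strictly increasing")
        if self.assay not in VALID_ASSAYS:
            raise ValueError(f"assay must be one of {VALID_ASSAYS}")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length must equal sample count")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicated sample_ids")
        if not self.cohort:
            self.cohort = [""] * n
        if not self.phase:
            self.phase = [""] * n

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_features(self) -> int:
        return self.intensities.shape[1]

    def nearest_feature(self, ppm: float) -> int:
        """Index of the grid point closest to `ppm`."""
        if not (self.ppm[0] <= ppm <= self.ppm[-1]):
            raise ValueError(f"{ppm} ppm outside axis range "
                             f"[{self.ppm[0]:.3f}, {self.ppm[-1]:.3f}]")
        return int(np.argmin(np.abs(self.ppm - ppm)))

    def subset(self, sample_ids: list[str]) -> "SpectrumSet":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [idx[s] for s in sample_ids]
        return SpectrumSet(
            self.intensities[rows],
            self.ppm,
            self.assay,
            list(sample_ids),
            [self.cohort[i] for i in rows],
            [self.phase[i] for i in rows],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.intensities, index=self.sample_ids,
                            columns=self.ppm)

    def to_tsv(self, path) -> None:
        """Write as TSV: first column sample_id, headers = ppm (descending)."""
        df = pd.DataFrame(self.intensities[:, ::-1], columns=[f"{p:.6f}" for p in self.ppm[::-1]])
        df.insert(0, "sample_id", self.sample_ids)
        df.insert(1, "cohort", self.cohort)
        df.insert(2, "phase", self.phase)
        with open(path, "w") as fh:
            fh.write(f"# assay={self.assay}\tppm_order=descending\n")
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "SpectrumSet":
        with open(path) as fh:
            first = fh.readline()
            assay = "standard1d"
            if first.startswith("#"):
                for tok in first[1:].split():
                    if tok.startswith("assay="):
                        assay = tok.split("=", 1)[1]
                df = pd.read_csv(fh, sep="\t")
            else:
                fh.seek(0)
                df = pd.read_csv(fh, sep="\t")
        sample_ids = df["sample_id"].astype(str).tolist()
        cohort = df["cohort"].astype(str).tolist() if "cohort" in df else []
        phase = df["phase"].astype(str).tolist() if "phase" in df else []
        value_cols = [c for c in df.columns if c not in ("sample_id", "cohort", "phase")]
        ppm = np.array([float(c) for c in value_cols])
        inten = df[value_cols].to_numpy(dtype=float)
        order = np.argsort(ppm)
        return cls(inten[:, order], ppm[order], assay, sample_ids, cohort, phase)
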