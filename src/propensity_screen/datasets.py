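"""In-memory containers for the expression and methylation data.

Expression data is held as dense arrays shaped ``(n_probes, n_lines, n_reps)``
so that per-line summaries and per-array (line, replicate) operations are
plain axis reductions.  Methylation data uses ``(n_probes, n_groups, n_reps)``
with the probe annotation manifest as a pandas DataFrame indexed by probe id.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError

PRESENT, ABSENT, MARGINAL = "P", "A", "M"
CALL_VALUES = frozenset({PRESENT, ABSENT, MARGINAL})

#: Fixed seven-category vocabulary for genomic-region assignment.
REGION_CATEGORIES = (
    "TSS1500",
    "TSS200",
    "5'UTR",
    "1stExon",
    "Body",
    "3'UTR",
    "intergenic",
)

#: Priority used to collapse multi-region probe annotations to one category.
#: Promoter-proximal annotations win; probes with no gene association fall
#: through to "intergenic".
REGION_PRIORITY = ("TSS200", "TSS1500", "5'UTR", "1stExon", "Body", "3'UTR")

ISLAND_RELATIONS = ("Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea")


@dataclass
class ExpressionDataset:
    """Probe-level intensities plus detection calls over (line, replicate)."""

    intensity: np.ndarray  # (n_probes, n_lines, n_reps), float, >= 0
    calls: np.ndarray  # (n_probes, n_lines, n_reps), unicode in {P, A, M}
    probe_ids: list[str]
    lines: list[str]
    normalized: bool = False

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.calls = np.asarray(self.calls, dtype="U1")
        if self.intensity.shape != self.calls.shape:
            raise ConfigError(
                f"intensity shape {self.intensity.shape} != calls shape {self.calls.shape}"
            )
        if self.intensity.ndim != 3:
            raise ConfigError("expression arrays must be (n_probes, n_lines, n_reps)")
        if self.intensity.shape[0] != len(self.probe_ids):
            raise ConfigError("probe_ids length does not match intensity")
        if self.intensity.shape[1] != len(self.lines):
            raise ConfigError("lines length does not match intensity")
        if np.any(self.intensity < 0):
            raise ConfigError("intensities must be non-negative")
        bad = set(np.unique(self.calls)) - CALL_VALUES
        if bad:
            raise ConfigError(f"unknown call values: {sorted(bad)}")
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise ConfigError("duplicate probe ids in ExpressionDataset")

    @property
    def n_probes(self) -> int:
        return self.intensity.shape[0]

    @property
    def n_lines(self) -> int:
        return self.intensity.shape[1]

    @property
    def n_replicates(self) -> int:
        return self.intensity.shape[2]

    def probe_index(self, probes) -> np.ndarray:
        """Integer positions of the given probe ids (order preserved)."""
        lookup = {p: i for i, p in enumerate(self.probe_ids)}
        try:
            return np.array([lookup[p] for p in probes], dtype=int)
        except KeyError as exc:  # pragma: no cover - defensive
            raise ConfigError(f"unknown probe id {exc.args[0]!r}") from None

    def line_means(self, probes=None) -> pd.DataFrame:
        """Mean intensity over replicates, per line; rows=probes, cols=lines."""
        if probes is None:
            idx = slice(None)
            ids = self.probe_ids
        else:
            idx = self.probe_index(probes)
            ids = list(probes)
        means = self.intensity[idx].mean(axis=2)
        return pd.DataFrame(means, index=ids, columns=self.lines)

    def copy(self) -> "ExpressionDataset":
        return ExpressionDataset(
            intensity=self.intensity.copy(),
            calls=self.calls.copy(),
            probe_ids=list(self.probe_ids),
            lines=list(self.lines),
            normalized=self.normalized,
        )


@dataclass
class MethylationDataset:
    """Beta values in [0, 1] over (group, replicate), with detection P and manifest.

    ``manifest`` is indexed by probe id with columns CHR, MAPINFO,
    UCSC_RefGene_Name, UCSC_RefGene_Group, Relation_to_UCSC_CpG_Island
    (HM450 manifest conventions; MAPINFO is 1-based). Missing chromosome or
    locus annotations are empty strings / NaN.
    """

    beta: np.ndarray  # (n_probes, n_groups, n_reps)
    detection_p: np.ndarray  # same shape
    manifest: pd.DataFrame
    probe_ids: list[str]
    groups: list[str] = field(default_factory=lambda: ["control", "knockdown"])
    clip_count: int = 0  # out-of-range draws clipped back into (0, 1)

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.detection_p = np.asarray(self.detection_p, dtype=float)
        if self.beta.shape != self.detection_p.shape:
            raise ConfigError("beta and detection_p shapes differ")
        if self.beta.ndim != 3:
            raise ConfigError("beta must be (n_probes, n_groups, n_reps)")
        if self.beta.shape[0] != len(self.probe_ids):
            raise ConfigError("probe_ids length does not match beta")
        if self.beta.shape[1] != len(self.groups):
            raise ConfigError("groups length does not match beta")
        if np.any(self.beta < 0) or np.any(self.beta > 1):
            raise ConfigError("beta values must lie in [0, 1]")

    @property
    def n_probes(self) -> int:
        return self.beta.shape[0]

    @property
    def n_replicates(self) -> int:
        return self.beta.shape[2]
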