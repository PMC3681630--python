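"""Simulation configuration for the synthetic array / annotation / qPCR generator.

The defaults describe the array design the pipeline was written for: 5,003
genes of *Clostridium beijerinckii* NCIMB 8052, five identical probe
replicates per gene, and one pooled control plus one pooled treatment array
for each of two growth phases (acidogenic, solventogenic).  Differential
expression is spiked as uniform log2 fold changes between a 3-fold floor and
the largest folds reported for each phase (16- and 54-fold).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

PerPhase = Union[float, Sequence[float]]
PerPhaseInt = Union[int, Sequence[int]]

#: Default per-phase (control, treatment) multiplicative slide scales.
#: Treatment slides are deliberately off-scale so that the scale-factor
#: normalization step has real work to do.
DEFAULT_ARRAY_SCALES = ((1.0, 0.8), (1.0, 1.25))


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic experiment.

    Per-phase parameters (``de_fraction_*``, ``fc_log2_*``, ``qpcr_gene_count``,
    ``array_scales``) accept either a scalar, applied to every phase, or a
    sequence with one entry per phase.
    """

    # --- array design -----------------------------------------------------
    n_genes: int = 5003
    n_probe_reps: int = 5
    phases: tuple[str, ...] = ("acidogenic", "solventogenic")

    # --- differential-expression spike model ------------------------------
    de_fraction_up: PerPhase = (0.011, 0.072)
    de_fraction_down: PerPhase = (0.011, 0.072)
    fc_log2_min: PerPhase = math.log2(3.0)
    fc_log2_max: PerPhase = (math.log2(16.0), math.log2(54.0))

    # --- signal model (log2 scale unless noted) ---------------------------
    baseline_log2_mean: float = 10.0
    baseline_log2_sd: float = 1.5
    probe_affinity_sd: float = 0.25
    noise_sd: float = 0.2
    array_scales: Sequence[Sequence[float]] = DEFAULT_ARRAY_SCALES
    signal_floor: float = 1.0
    outlier_prob: float = 0.01
    outlier_log2_shift: float = 4.0

    # --- term annotation model --------------------------------------------
    n_terms: int = 50
    term_size_min: int = 10
    term_size_max: int = 80
    n_enriched_terms: int = 5
    enrichment_boost: float = 20.0

    # --- qPCR model --------------------------------------------------------
    qpcr_gene_count: PerPhaseInt = (19, 23)
    qpcr_wells: int = 3
    qpcr_ct_sd: float = 0.15
    qpcr_ref_ct: float = 12.0
    qpcr_target_ct_offset: float = 30.0
    reference_gene: str = "16S_rRNA"

    seed: int = 0

    # ------------------------------------------------------------------
    @property
    def n_phases(self) -> int:
        return len(self.phases)

    def per_phase(self, name: str) -> tuple:
        """Expand a scalar-or-sequence field to one value per phase."""
        value = getattr(self, name)
        if isinstance(value, (int, float)):
            return tuple(value for _ in self.phases)
        value = tuple(value)
        if len(value) != self.n_phases:
            raise ValueError(
                f"{name} has {len(value)} entries for {self.n_phases} phases"
            )
        return value

    def validate(self) -> "SimulationConfig":
        """Check invariants; returns self so calls can be chained."""
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.n_probe_reps < 3:
            raise ValueError("n_probe_reps must be >= 3 (trimming needs 3)")
        if self.n_phases < 1:
            raise ValueError("at least one phase required")
        if len(set(self.phases)) != self.n_phases:
            raise ValueError("phase labels must be unique")
        ups = self.per_phase("de_fraction_up")
        downs = self.per_phase("de_fraction_down")
        for up, down in zip(ups, downs):
            if not (0.0 <= up <= 1.0 and 0.0 <= down <= 1.0):
                raise ValueError("DE fractions must lie in [0, 1]")
            if up + down >= 1.0:
                raise ValueError("de_fraction_up + de_fraction_down must be < 1")
        for lo, hi in zip(self.per_phase("fc_log2_min"), self.per_phase("fc_log2_max")):
            if lo < 0:
                raise ValueError("fc_log2_min must be >= 0")
            if hi < lo:
                raise ValueError("fc_log2_max must be >= fc_log2_min")
        if not 0.0 <= self.outlier_prob <= 1.0:
            raise ValueError("outlier_prob must lie in [0, 1]")
        for sd in (self.baseline_log2_sd, self.probe_affinity_sd, self.noise_sd,
                   self.qpcr_ct_sd):
            if sd < 0:
                raise ValueError("standard deviations must be >= 0")
        scales = self.per_phase("array_scales")
        for pair in scales:
            if len(tuple(pair)) != 2:
                raise ValueError("array_scales needs (control, treatment) per phase")
            if min(pair) <= 0:
                raise ValueError("array scales must be positive")
        if self.signal_floor <= 0:
            raise ValueError("signal_floor must be positive")
        if not 1 <= self.term_size_min <= self.term_size_max <= self.n_genes:
            raise ValueError("term sizes must satisfy 1 <= min <= max <= n_genes")
        if self.n_enriched_terms * self.n_phases > self.n_terms:
            raise ValueError("more enriched terms requested than terms exist")
        for count in self.per_phase("qpcr_gene_count"):
            if not 0 <= count <= self.n_genes:
                raise ValueError("qpcr_gene_count must lie in [0, n_genes]")
        if self.qpcr_wells < 1:
            raise ValueError("qpcr_wells must be >= 1")
        return self

    # --- JSON round trip ---------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["phases"] = list(self.phases)
        d["array_scales"] = [list(p) for p in self.per_phase("array_scales")]
        for name in ("de_fraction_up", "de_fraction_down",
                     "fc_log2_min", "fc_log2_max", "qpcr_gene_count"):
            d[name] = list(self.per_phase(name))
        return d

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(
            json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n"
        )

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(d)
        if "phases" in kwargs:
            kwargs["phases"] = tuple(kwargs["phases"])
        if "array_scales" in kwargs:
            kwargs["array_scales"] = tuple(
                tuple(p) for p in kwargs["array_scales"]
            )
        for name in ("de_fraction_up", "de_fraction_down",
                     "fc_log2_min", "fc_log2_max", "qpcr_gene_count"):
            if name in kwargs and isinstance(kwargs[name], list):
                kwargs[name] = tuple(kwargs[name])
        return cls(**kwargs).validate()

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "SimulationConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def replace(self, **changes) -> "SimulationConfig":
        return dataclasses.replace(self, **changes)
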