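"""Run configuration: every filtering threshold used across the pipeline.

Defaults reproduce the published analysis settings for MIDAS-style gut
metagenome tables. A config can be loaded from / dumped to YAML so that a
whole run is reproducible from one text file plus one seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    # --- site / sample coverage filters (SNV stage) ---
    site_depth_lo_frac: float = 0.3   # retain site iff 0.3*Dbar <= D
    site_depth_hi_frac: float = 3.0   # ... and D <= 3*Dbar
    min_median_depth: float = 5.0     # drop sample iff Dbar < 5

    # --- species eligibility ---
    min_marker_coverage: float = 10.0  # marker coverage >= 10 ...
    min_eligible_samples: int = 10     # ... in >= 10 samples

    # --- polymorphism window ---
    freq_lo: float = 0.2              # intermediate-frequency window,
    freq_hi: float = 0.8              # inclusive at both ends

    # --- gene copy-number stage ---
    prevalence_c_lo: float = 0.3      # prevalence counts samples with
    prevalence_c_hi: float = 3.0      # 0.3 <= c <= 3 ...
    prevalence_min_marker: float = 5.0  # ... given marker coverage >= 5
    core_prevalence: float = 0.9      # core gene: prevalence >= 90%
    high_copy_cutoff: float = 3.0     # exclude gene if c >= 3 anywhere
    absence_c_max: float = 0.05       # absent: c <= 0.05
    presence_c_lo: float = 0.6        # present: 0.6 <= c <= 1.2 ...
    presence_c_hi: float = 1.2
    presence_min_marker: float = 20.0  # ... with marker coverage >= 20
    call_min_marker: float = 5.0      # any call needs marker >= 5, else ambiguous

    # --- strain inference ---
    strain_min_depth: int = 20        # multi-allelic sites need D >= 20
    strain_min_sites: int = 100       # species/sample pairs below floor dropped
    strain_k_max: int = 4             # K in {1..4}
    strain_n_restarts: int = 10
    strain_tol: float = 1e-6
    strain_eps_max: float = 0.1
    count_floor_multiallelic_only: bool = True  # 100-site floor counts
    # multi-allelic sites (default) or all >=20x sites
    strain_selection: str = "marginal_bic"  # or "profile_bic"

    # --- diversity ---
    rarefaction_depth: int = 5_000_000  # dense time-series default; the
    # cross-sectional cohort used 20M
    shannon_base: float | None = None   # None -> natural log

    # --- temporal pairing ---
    anchor_first_only: bool = False   # polymorphism change: pair every earlier
    # time point with later ones (False) or only the first sample (True)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(data) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**data)


DEFAULT_CONFIG = RunConfig()
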