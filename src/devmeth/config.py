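"""Pipeline configuration with study-default thresholds.

Defaults mirror the analysis conventions of the mouse cortex study design:
detection P 0.05, >5% inner-80% variability rule, 1500 bp DMR gap, nominal
P 0.05, ANOVA site-selection P 1e-8, top-50 sites per direction, and a
10-gene minimum for tested GO terms.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields

import yaml


class ConfigError(ValueError):
    pass


@dataclass
class Config:
    # sample QC
    min_median_intensity: float = 2000.0
    max_detection_fail_frac: float = 0.01
    min_bisulfite_pct: float = 90.0
    detection_p: float = 0.05
    # probe filtering / variability
    max_detection_fail_samples: int = 1   # fail in MORE than this many -> removed
    variable_min_range: float = 0.05
    inner_fraction: float = 0.8
    # deconvolution
    anova_p: float = 1e-8
    top_k: int = 50
    # differential / DMR
    alpha: float = 0.05
    n_tests: int | None = None            # Bonferroni override (default: probes tested)
    dmr_gap_bp: int = 1500
    nominal_p: float = 0.05
    # enrichment
    min_term_genes: int = 10
    # run control
    seed: int = 0
    out_dir: str = "results"
    # simulation design overrides
    n_probes: int = 5000
    n_per_cell: int = 5


def load_config(path=None) -> Config:
    """Load a YAML key/value config; unset keys take the study defaults.

    An unknown key is an error that lists the valid keys.
    """
    if path is None:
        return Config()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} must be a key/value mapping")
    valid = {f.name for f in fields(Config)}
    unknown = set(raw) - valid
    if unknown:
        raise ConfigError(
            f"unknown config keys {sorted(unknown)}; valid keys: {sorted(valid)}")
    return Config(**raw)


def config_to_dict(cfg: Config) -> dict:
    return asdict(cfg)
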