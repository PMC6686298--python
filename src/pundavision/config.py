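"""Run configuration: validated thresholds and constants, YAML round-trip."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .io_formats import OPSINS

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config"]


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """All tunables of a pipeline run.

    Defaults are the published analysis constants: efficiency band 75-125%
    ((E-1)*100 convention), duplicate Ct SD at most 0.5 cycles, 1.5 x IQR
    outlier fence, orange-ratio bands 550-700 / 400-549 nm, A1 pigment peaks
    425/455/528 nm plus LWS-by-genotype 559 (H) / 544 (P).
    """

    efficiency_band_pct: tuple = (75.0, 125.0)
    max_ct_sd: float = 0.5
    iqr_multiplier: float = 1.5
    iqr_drop: str = "opsin"  # "opsin": flagged value -> that opsin missing;
    #                          "fish": flagged value -> whole fish dropped
    baseline_cycles: int = 3
    primer_mismatches: int = 0  # anchoring tolerance for genotyping
    expression_transform: str = "identity"  # or "logit", applied before LMs
    lambda_max: dict = field(
        default_factory=lambda: {"SWS2b": 425.0, "SWS2a": 455.0, "RH2A": 528.0}
    )
    lws_allele_lambda_max: dict = field(
        default_factory=lambda: {"H": 559.0, "P": 544.0}
    )
    or_numerator_band: tuple = (550.0, 700.0)
    or_denominator_band: tuple = (400.0, 549.0)
    n_perm: int = 999
    stats_seed: int = 0
    alpha: float = 0.05
    stages: tuple = ("quantify", "genotype", "light", "visual", "stats")

    def validate(self) -> None:
        lo, hi = self.efficiency_band_pct
        if not (0 < lo < hi):
            raise ConfigError(f"bad efficiency band {self.efficiency_band_pct}")
        if self.max_ct_sd <= 0 or self.iqr_multiplier <= 0:
            raise ConfigError("QC thresholds must be positive")
        missing = [o for o in OPSINS if o != "LWS" and o not in self.lambda_max]
        if missing:
            raise ConfigError(f"lambda_max missing for opsin(s): {', '.join(missing)}")
        for allele in ("H", "P"):
            if allele not in self.lws_allele_lambda_max:
                raise ConfigError(f"lws_allele_lambda_max missing allele {allele}")
        if self.n_perm < 999:
            raise ConfigError("n_perm must be >= 999")
        if self.iqr_drop not in ("opsin", "fish"):
            raise ConfigError(f"iqr_drop must be 'opsin' or 'fish', got {self.iqr_drop!r}")
        if self.expression_transform not in ("identity", "logit"):
            raise ConfigError(
                f"expression_transform must be 'identity' or 'logit', "
                f"got {self.expression_transform!r}"
            )
        if self.primer_mismatches < 0:
            raise ConfigError("primer_mismatches must be >= 0")

    def config_hash(self) -> str:
        payload = yaml.safe_dump(_to_plain(asdict(self)), sort_keys=True)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


def _to_plain(obj):
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = RunConfig.__dataclass_fields__
    bad = set(raw) - set(known)
    if bad:
        raise ConfigError(f"unknown config key(s): {', '.join(sorted(bad))}")
    tuple_fields = {"efficiency_band_pct", "or_numerator_band",
                    "or_denominator_band", "stages"}
    cfg = RunConfig(**{
        k: tuple(v) if k in tuple_fields and isinstance(v, list) else v
        for k, v in raw.items()
    })
    cfg.validate()
    return cfg


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_to_plain(asdict(cfg)), sort_keys=True))
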