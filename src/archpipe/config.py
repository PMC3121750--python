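"""Run configuration: YAML mapping with strict keys and seed splitting.

Every stage receives its own child seed derived from the master seed via
``numpy.random.SeedSequence(master).spawn``: stage ``i`` in the fixed
stage order gets child ``i``, so adding randomness to one stage never
perturbs another.
"""

from __future__ import annotations

import copy
from pathlib import Path

import numpy as np
import yaml

__all__ = ["DEFAULT_CONFIG", "RunConfig"]

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "out_dir": "archpipe_run",
    "cohort": {
        "m": 2000,
        "m_causal": 100,
        "h2_l": 0.3,
        "K": 0.05,
        "n_case": 500,
        "n_control": 2000,
        "maf_low": 0.05,
        "maf_high": 0.5,
    },
    "external_cohort": {"n_case": 300, "n_control": 1200},
    "platform": {
        "frac_platform2": 0.3,
        "missing_v1": 0.005,
        "missing_v2": 0.02,
        "error_rate": 0.0,
    },
    "qc": {"min_call_rate": 0.95, "min_maf": 0.001, "hwe_alpha": 1e-6},
    "mds": {"k": 5},
    "assoc": {"covariates": ["sex", "age", "pc1", "pc2", "pc3", "pc4", "pc5"]},
    # at desk-scale SNP counts the GRM sampling noise is ~1/sqrt(m), so the
    # production relatedness cutoff 0.025 would prune unrelated samples;
    # the default here is several sampling SDs for m in the low thousands
    "greml": {"prune_threshold": 0.2, "max_n": 4000, "n_pcs": 5},
    "risk": {"efp_grid": [0.05, 0.5, 5.0, 50.0, 500.0], "n_folds": 5},
    "auc": {"n_boot": 200},
    "family": {"h2": 0.3, "children": 3, "n_families": 200_000},
    "liability": {"K": 0.01},
}

#: stage order used for seed splitting (index = spawn child index)
STAGES = ("cohort", "platform", "external", "greml", "risk", "auc", "family")


class RunConfig:
    """Validated pipeline settings; unknown keys are rejected."""

    def __init__(self, overrides: dict | None = None):
        cfg = copy.deepcopy(DEFAULT_CONFIG)
        if overrides:
            _merge_strict(cfg, overrides, path="")
        self.data = cfg
        self._children = np.random.SeedSequence(cfg["seed"]).spawn(len(STAGES))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            overrides = yaml.safe_load(fh) or {}
        if not isinstance(overrides, dict):
            raise ValueError("run configuration must be a YAML mapping")
        return cls(overrides)

    def __getitem__(self, key: str):
        return self.data[key]

    def stage_seed(self, stage: str) -> int:
        """Deterministic 31-bit child seed for a named stage."""
        idx = STAGES.index(stage)
        return int(self._children[idx].generate_state(1)[0] % (2**31))


def _merge_strict(base: dict, overrides: dict, path: str) -> None:
    for key, val in overrides.items():
        if key not in base:
            raise KeyError(f"unknown configuration key: {path + key!r}")
        if isinstance(base[key], dict):
            if not isinstance(val, dict):
                raise ValueError(f"configuration key {path + key!r} must be a mapping")
            _merge_strict(base[key], val, path + key + ".")
        else:
            base[key] = val
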