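"""Run configuration: input paths and every pipeline threshold.

Defaults are the values used throughout the analysis: loop q < 0.01, FIMO
p <= 1e-4 / q <= 5e-2, FPKM > 0.003 in every replicate, 5-kb anchor padding,
10-kb minimum and 3-Mb maximum separation, 10-kb annotation gaps, 15-kb
enhancer-hotspot and 20-kb eQTL-cluster merge gaps, 1000 specificity
permutations and 10,000 NMI randomizations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

_INPUT_KEYS = (
    "loops", "pair_counts", "enhancer_peaks", "ctcf_peaks", "gene_models",
    "motif_hits", "ppi", "expression", "snps", "oncogenes", "de_labels",
)


@dataclass
class RunConfig:
    inputs: dict = field(default_factory=dict)
    out_dir: str = "penguin_out"
    seed: int = 0
    loop_max_q: float = 0.01
    fimo_max_p: float = 1e-4
    fimo_max_q: float = 5e-2
    min_fpkm: float = 0.003
    anchor_pad: int = 5000
    promoter_halfwidth: int = 500
    min_sep: int = 10_000
    max_sep: int = 3_000_000
    beta_min: float = 1e-3
    prioritize_fraction: float = 0.8
    ctcf_gap: int = 10_000
    snp_gap: int = 10_000
    hotspot_gap: int = 15_000
    eqtl_gap: int = 20_000
    k: int = 2
    alpha_branch: float = 0.001
    alpha_specific: float = 0.01
    n_perm: int = 1000
    n_rand: int = 10_000

    def __post_init__(self) -> None:
        problems = []
        for key in self.inputs:
            if key not in _INPUT_KEYS:
                problems.append(f"unknown input key {key!r}")
        checks = [
            (0 <= self.loop_max_q <= 1, "loop_max_q in [0,1]"),
            (0 < self.fimo_max_p <= 1, "fimo_max_p in (0,1]"),
            (0 < self.fimo_max_q <= 1, "fimo_max_q in (0,1]"),
            (self.min_fpkm >= 0, "min_fpkm >= 0"),
            (self.anchor_pad >= 0, "anchor_pad >= 0"),
            (0 <= self.min_sep < self.max_sep, "0 <= min_sep < max_sep"),
            (self.beta_min > 0, "beta_min > 0"),
            (0 < self.prioritize_fraction <= 1, "prioritize_fraction in (0,1]"),
            (self.k >= 2, "k >= 2"),
            (0 < self.alpha_branch <= 1, "alpha_branch in (0,1]"),
            (0 < self.alpha_specific <= 1, "alpha_specific in (0,1]"),
            (self.n_perm >= 1, "n_perm >= 1"),
            (self.n_rand >= 1, "n_rand >= 1"),
        ]
        problems.extend(msg for ok, msg in checks if not ok)
        if problems:
            raise ValueError("invalid configuration: " + "; ".join(problems))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = {f.name: getattr(self, f.name) for f in fields(self)}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    def input_path(self, key: str) -> Path:
        if key not in self.inputs:
            raise ValueError(f"input {key!r} not configured")
        p = Path(self.inputs[key])
        if not p.exists():
            raise FileNotFoundError(f"input {key!r} not found at {p}")
        return p
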