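"""Single configuration object covering every tunable threshold.

Defaults reproduce the synopsis' stated settings: two-sided alpha 0.05 for
pooled tests, bias tests read at 0.10, the fixed/random model switch at
I^2 = 50%, FPRP prior 0.05 with power target OR 1.2 and category cutoffs
0.05/0.20, HWE exclusion at p < 0.05 in controls, and meta-analyses
requiring at least three datasets.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .grading import VeniceThresholds


@dataclass
class SynopsisConfig:
    alpha: float = 0.05  # two-sided significance for pooled tests
    bias_alpha: float = 0.10  # Egger/Begg significance level
    switch_i2: float = 50.0  # random-effects switch (I^2 percent)
    hwe_alpha: float = 0.05  # HWE exclusion cutoff in controls
    min_datasets: int = 3  # eligibility for a main meta-analysis
    fprp_pi: float = 0.05  # FPRP prior probability
    fprp_or1: float = 1.2  # FPRP power target odds ratio
    fprp_alpha_source: str = "reported_p"  # or "ci_implied"
    venice: VeniceThresholds = field(default_factory=VeniceThresholds)
    #: per-variant designated effect (minor) allele, e.g. {"rs2228145": "C"}
    effect_alleles: dict[str, str] = field(default_factory=dict)
    #: per-variant minor-allele frequency used for amount-of-evidence grading
    mafs: dict[str, float] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "SynopsisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        venice = VeniceThresholds(**raw.pop("venice", {}))
        return cls(venice=venice, **raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
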