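"""Run configuration: serialisable settings for reproducible batch runs."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .eeq import BACKEND_TAG
from .energy import ParameterSet
from .io import DEFAULT_SEED


@dataclass
class RunConfig:
    """Everything a run needs to be repeated exactly.

    ``donor_scope`` chooses whether only X-H (X != C) or all hydrogens
    enter the polar term; ``donor_aggregation`` chooses how several
    hydrogens on one heavy atom collapse to one donor strength;
    ``r2_definition`` selects the reported coefficient of determination.
    """

    backend: str = "eeq"
    seed: int = DEFAULT_SEED
    params: ParameterSet = field(default_factory=ParameterSet)
    donor_scope: str = "xh-only"          # xh-only | all-h
    donor_aggregation: str = "mean"       # mean | max
    r2_definition: str = "pearson-squared"  # pearson-squared | ss-based

    def to_dict(self) -> dict:
        d = asdict(self)
        d["package_version"] = __version__
        d["backend_version"] = BACKEND_TAG
        return d

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        data.pop("package_version", None)
        data.pop("backend_version", None)
        params = data.pop("params", None)
        cfg = cls(**data)
        if params is not None:
            cfg.params = ParameterSet.from_dict(params)
        return cfg
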