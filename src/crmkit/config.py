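"""Configuration resolution: files, flags, defaults, cross-field checks.

Design parameters may come from a YAML or JSON config file, from CLI
flags, or both (flags override file values).  Defaults applied here are
the package's recommended design: indifference half-width ``delta=0.05``,
prior MTD at the median dose ``nu = ceil(K/2)``, and the least-informative
prior SD calibrated from the resulting skeleton.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .calibration import SkeletonRequest, generate_skeleton, least_informative_sigma
from .engine import DesignSpec, TrialState
from .errors import InvalidDesignError

__all__ = ["load_config", "resolve_design", "resolve_state", "median_dose"]


def median_dose(K: int) -> int:
    """Default prior-MTD index: the median dose, ceil(K/2)."""
    return math.ceil(K / 2)


def load_config(path: str | Path) -> dict[str, Any]:
    """Read a YAML (or JSON) config file into a flat mapping."""
    path = Path(path)
    if not path.exists():
        raise InvalidDesignError(f"config file not found: {path}")
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise InvalidDesignError(f"config file {path} must contain a mapping")
    return data


def resolve_design(
    target: float,
    n_doses: int | None = None,
    *,
    skeleton: list[float] | tuple[float, ...] | None = None,
    delta: float = 0.05,
    nu: int | None = None,
    sigma: float | None = None,
    start_dose: int = 1,
    cohort_size: int = 2,
    max_n: int = 24,
    stop_count: int | None = None,
) -> DesignSpec:
    """Build a fully-resolved :class:`DesignSpec` with defaults applied.

    Either an explicit ``skeleton`` or ``n_doses`` must be given; in the
    latter case the skeleton is generated by the indifference-interval
    recursion with half-width ``delta`` and prior MTD ``nu`` (default: the
    median dose).  ``sigma`` defaults to the calibrated least-informative
    value.  ``stop_count`` defaults to ``max_n + 1`` so the rule never
    binds unless requested.
    """
    if skeleton is None:
        if n_doses is None:
            raise InvalidDesignError(
                "either a skeleton or the number of dose levels must be given"
            )
        req = SkeletonRequest(
            delta=delta, theta=target, nu=nu if nu is not None else median_dose(n_doses),
            K=n_doses,
        )
        sk = generate_skeleton(req)
    else:
        sk = np.asarray(skeleton, dtype=float)
        if n_doses is not None and n_doses != sk.size:
            raise InvalidDesignError(
                "length of the skeleton should be equal to the number of possible "
                "study dose levels"
            )
    if sigma is None:
        if sk.size == 1:
            sigma = 1.0  # degenerate single-dose design: prior SD is immaterial
        else:
            sigma = least_informative_sigma(sk, target)
    if stop_count is None:
        stop_count = max_n + 1
    return DesignSpec(
        theta=target,
        skeleton=tuple(float(v) for v in sk),
        sigma_a=float(sigma),
        start_dose=start_dose,
        cohort_size=cohort_size,
        max_n=max_n,
        stop_count=stop_count,
    )


def resolve_state(
    dlts: list[int] | tuple[int, ...],
    patients: list[int] | tuple[int, ...],
    current_dose: int,
    K: int,
) -> TrialState:
    """Validate accumulated trial data against the design's dose count."""
    if len(dlts) != K:
        raise InvalidDesignError(
            "length of the DLT set should be equal to the number of possible "
            "study dose levels"
        )
    if len(patients) != K:
        raise InvalidDesignError(
            "length of the patients set should be equal to the number of possible "
            "study dose levels"
        )
    return TrialState(y=tuple(dlts), n=tuple(patients), current_dose=current_dose)
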