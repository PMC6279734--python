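"""Simulated study cohorts: per-subject functional parameters drawn from
group-level means and SDs.

Each parameter is drawn independently Gaussian(mean, SD); a subject draw
is redrawn until its CurveSpec satisfies the curve-family invariants
(EDV > ESV > 0, TPFR within the cycle, PFR >= 1/3MFR).  More than 100
consecutive infeasible draws raise an error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from ..errors import DataError, InfeasibleSpecError
from .synthesis import CurveSpec

__all__ = ["ParameterSpec", "CohortSpec", "sample_cohort"]

ParameterSpec = Tuple[float, float]  # (mean, SD)


@dataclass(frozen=True)
class CohortSpec:
    """Group-level distribution of functional parameters.

    Each of edv, esv, hr, pfr, third_mfr, tpfr is a (mean, SD) pair;
    pfr/third_mfr/tpfr may be None to leave the curve unconstrained there.
    """

    edv: ParameterSpec
    esv: ParameterSpec
    hr: ParameterSpec
    pfr: Optional[ParameterSpec] = None
    third_mfr: Optional[ParameterSpec] = None
    tpfr: Optional[ParameterSpec] = None
    n_subjects: int = 6
    seed: int = 0
    name: str = ""

    def __post_init__(self):
        for pname in ("edv", "esv", "hr", "pfr", "third_mfr", "tpfr"):
            p = getattr(self, pname)
            if p is None:
                continue
            mean, sd = p
            if sd < 0:
                raise DataError(f"{pname}: SD must be >= 0, got {sd}")
        if self.n_subjects < 2:
            raise DataError("n_subjects must be >= 2")


def sample_cohort(spec: CohortSpec, seed: Optional[int] = None,
                  max_redraws: int = 100) -> List[CurveSpec]:
    """Draw one feasible CurveSpec per subject; seeded and reproducible."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    subjects = []
    for _ in range(spec.n_subjects):
        for attempt in range(max_redraws + 1):
            draw = {}
            for pname in ("edv", "esv", "hr", "pfr", "third_mfr", "tpfr"):
                p = getattr(spec, pname)
                if p is None:
                    draw[pname] = None
                else:
                    mean, sd = p
                    draw[pname] = float(rng.normal(mean, sd)) if sd > 0 else float(mean)
            cs = CurveSpec(edv=draw["edv"], esv=draw["esv"],
                           heart_rate=draw["hr"], pfr=draw["pfr"],
                           third_mfr=draw["third_mfr"], tpfr=draw["tpfr"])
            try:
                cs.validate()
            except InfeasibleSpecError:
                continue
            subjects.append(cs)
            break
        else:
            raise InfeasibleSpecError(
                f"more than {max_redraws} consecutive infeasible draws from "
                f"cohort {spec.name or '<unnamed>'}")
    return subjects
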