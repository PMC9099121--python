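"""Population and individual pharmacokinetic parameter containers.

The population model is a three-compartment disposition model with linear
elimination and first-order absorption preceded by a continuous chain of
transit compartments.  All parameters are apparent (divided by the oral
bioavailability F, which is fixed to 1).  Baseline serum albumin acts as a
power-law covariate on apparent clearance, normalised at a reference of
41 g/L.  Inter-individual variability is log-normal on CL/F, V1/F, V2/F,
the transit-compartment count and the mean transit time; the
intercompartmental clearances Q2/F, Q3/F and the second peripheral volume
V3/F carry no random effect.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

#: Order of the log-normal random effects (rows/columns of ``omega``).
ETA_NAMES: tuple[str, ...] = ("cl", "v1", "v2", "n_transit", "mtt")


def _default_asset() -> dict:
    ref = importlib.resources.files("brigex.data").joinpath("alta1l_poppk.yaml")
    return yaml.safe_load(ref.read_text())


@dataclass(frozen=True)
class PopPKParameters:
    """Fixed effects, random-effect variances and residual error of the
    population PK model.

    Typical values default to the geometric means estimated in the
    first-line ALK+ NSCLC population (CL/F 8.45 L/h, V1/F 160 L, ...).
    ``omega`` is the log-scale covariance matrix of the random effects in
    :data:`ETA_NAMES` order.
    """

    cl_typ: float = 8.45
    v1_typ: float = 160.0
    q2_typ: float = 12.6
    v2_typ: float = 118.0
    q3_typ: float = 2.67
    v3_typ: float = 78.5
    n_transit_typ: float = 2.76
    mtt_typ: float = 1.01
    ka_typ: float = 2.0
    alb_exp: float = 0.75
    alb_ref: float = 41.0
    omega: np.ndarray = field(
        default_factory=lambda: np.diag([0.2025, 0.2025, 0.3025, 0.1225, 0.2025])
    )
    sigma_prop: float = 0.30
    sigma_add: float = 1.0
    lloq: float = 5.0

    def __post_init__(self) -> None:
        for name in (
            "cl_typ", "v1_typ", "q2_typ", "v2_typ", "q3_typ", "v3_typ",
            "n_transit_typ", "mtt_typ", "ka_typ", "alb_ref",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.sigma_prop < 0 or self.sigma_add < 0:
            raise ValueError("residual error SDs must be nonnegative")
        om = np.asarray(self.omega, dtype=float)
        if om.shape != (len(ETA_NAMES), len(ETA_NAMES)):
            raise ValueError(
                f"omega must be {len(ETA_NAMES)}x{len(ETA_NAMES)} "
                f"(eta order {ETA_NAMES})"
            )
        if not np.allclose(om, om.T):
            raise ValueError("omega must be symmetric")
        if np.linalg.eigvalsh(om).min() < -1e-10:
            raise ValueError("omega must be positive semidefinite")
        object.__setattr__(self, "omega", om)

    @classmethod
    def from_yaml(cls, path=None) -> "PopPKParameters":
        """Load parameters from a YAML file; defaults to the packaged asset."""
        if path is None:
            raw = _default_asset()
        else:
            with open(path) as fh:
                raw = yaml.safe_load(fh)
        omega_map = raw.pop("omega", {})
        om = np.zeros((len(ETA_NAMES), len(ETA_NAMES)))
        for i, name in enumerate(ETA_NAMES):
            om[i, i] = float(omega_map.get(name, 0.0))
        return cls(omega=om, **raw)

    def with_overrides(self, **kwargs) -> "PopPKParameters":
        return replace(self, **kwargs)

    @property
    def omega_sd(self) -> np.ndarray:
        return np.sqrt(np.diag(self.omega))


@dataclass(frozen=True)
class IndividualPKParameters:
    """Individual-scale PK parameters (all strictly positive)."""

    cl: float
    v1: float
    q2: float
    v2: float
    q3: float
    v3: float
    n_transit: float
    mtt: float
    ka: float

    def __post_init__(self) -> None:
        for name in ("cl", "v1", "q2", "v2", "q3", "v3", "n_transit", "mtt", "ka"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


def apply_covariates_and_eta(
    pop: PopPKParameters, albumin: float, eta
) -> IndividualPKParameters:
    """Individualise the population parameters.

    CL/F is scaled by ``(albumin / alb_ref) ** alb_exp`` and, like V1/F,
    V2/F, the transit count and the mean transit time, multiplied by
    ``exp(eta)``.  Q2/F, Q3/F, V3/F and ka take their typical values.

    Parameters
    ----------
    albumin : float
        Baseline serum albumin in g/L (must be > 0).
    eta : array-like
        Random-effect vector in :data:`ETA_NAMES` order.
    """
    if albumin <= 0:
        raise ValueError("albumin must be strictly positive (g/L)")
    eta = np.asarray(eta, dtype=float)
    if eta.shape != (len(ETA_NAMES),):
        raise ValueError(f"eta must have length {len(ETA_NAMES)} ({ETA_NAMES})")
    e = dict(zip(ETA_NAMES, eta))
    alb_mult = (albumin / pop.alb_ref) ** pop.alb_exp
    return IndividualPKParameters(
        cl=pop.cl_typ * alb_mult * np.exp(e["cl"]),
        v1=pop.v1_typ * np.exp(e["v1"]),
        q2=pop.q2_typ,
        v2=pop.v2_typ * np.exp(e["v2"]),
        q3=pop.q3_typ,
        v3=pop.v3_typ,
        n_transit=pop.n_transit_typ * np.exp(e["n_transit"]),
        mtt=pop.mtt_typ * np.exp(e["mtt"]),
        ka=pop.ka_typ,
    )
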