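"""Three-population out-of-Africa demographic model and theta scaling.

The topology is fixed by the analysis design: an ancestral African
population that expands anciently, a single out-of-Africa bottleneck
founding a Eurasian population ("B") with symmetric African migration, and a
later split of B into European and East Asian populations, each with its own
founding bottleneck, exponential growth to the present, and pairwise
migration. Time is measured in generations before present internally; the
generation time (default 25 y) is used only for presentation.

Default parameter values reconstruct the published three-population fit of
Gutenkunst et al. (2009), uniformly rescaled so that the two anchors of the
fit used here hold exactly: ancestral diploid size 18,449 and oldest event
(the African expansion) 22,117 generations before present. Sizes scale by
18449/7300, times by 22117/8800; per-generation migration and growth rates
scale inversely so that the compound parameters (2Nm, total growth) are
preserved. Any other fit can be supplied via YAML.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, replace

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ThreePopModel",
    "ConstantModel",
    "ThetaScaling",
    "default_model",
    "size_at",
    "reference_ne",
    "rescale",
    "validate",
    "load_model",
    "save_model",
    "size_trajectory",
]

_SIZE_SCALE = 18449.0 / 7300.0
_TIME_SCALE = 22117.0 / 8800.0


@dataclass
class ThreePopModel:
    """Parametric AFR / (EUR, EASN) demographic model.

    Sizes are diploid; times are generations before present; migration rates
    are per-generation fractions of the receiving population replaced by
    migrants (symmetric per pair); growth rates are per-generation
    exponential rates running forward in time from each split.
    """

    n_anc: float
    n_afr: float
    t_expansion: float
    n_b: float
    t_ooa_split: float
    m_afr_b: float
    n_eur0: float
    r_eur: float
    n_easn0: float
    r_easn: float
    t_eur_easn_split: float
    m_afr_eur: float
    m_afr_easn: float
    m_eur_easn: float
    generation_time: float = 25.0

    @property
    def t_total(self) -> float:
        """Total simulated span: the oldest event, generations before present."""
        return self.t_expansion

    def final_size(self, pop: str) -> float:
        return size_at(self, pop, 0.0)


@dataclass
class ConstantModel:
    """Single population of constant size (equilibrium controls and tests)."""

    n: float
    generation_time: float = 25.0


def default_model() -> ThreePopModel:
    g = {  # Gutenkunst et al. 2009 YRI/CEU/CHB maximum-likelihood fit
        "n_anc": 7300.0, "n_afr": 12300.0, "t_expansion": 8800.0,
        "n_b": 2100.0, "t_ooa_split": 5600.0, "m_afr_b": 25e-5,
        "n_eur0": 1000.0, "r_eur": 0.004, "n_easn0": 510.0, "r_easn": 0.0055,
        "t_eur_easn_split": 848.0, "m_afr_eur": 3e-5, "m_afr_easn": 1.9e-5,
        "m_eur_easn": 9.6e-5,
    }
    return ThreePopModel(
        n_anc=g["n_anc"] * _SIZE_SCALE,
        n_afr=g["n_afr"] * _SIZE_SCALE,
        t_expansion=g["t_expansion"] * _TIME_SCALE,
        n_b=g["n_b"] * _SIZE_SCALE,
        t_ooa_split=g["t_ooa_split"] * _TIME_SCALE,
        m_afr_b=g["m_afr_b"] / _SIZE_SCALE,
        n_eur0=g["n_eur0"] * _SIZE_SCALE,
        r_eur=g["r_eur"] / _TIME_SCALE,
        n_easn0=g["n_easn0"] * _SIZE_SCALE,
        r_easn=g["r_easn"] / _TIME_SCALE,
        t_eur_easn_split=g["t_eur_easn_split"] * _TIME_SCALE,
        m_afr_eur=g["m_afr_eur"] / _SIZE_SCALE,
        m_afr_easn=g["m_afr_easn"] / _SIZE_SCALE,
        m_eur_easn=g["m_eur_easn"] / _SIZE_SCALE,
    )


def size_at(model: ThreePopModel | ConstantModel, pop: str, t: float) -> float:
    """Diploid size of a lineage ``t`` generations before present.

    Piecewise constant except for the exponential-growth epochs of EUR and
    EASN; times older than a lineage's origin follow its ancestor (B, then
    ancestral Africa).
    """
    if isinstance(model, ConstantModel):
        return model.n
    if t >= model.t_expansion:
        return model.n_anc
    if pop == "AFR":
        return model.n_afr
    if pop in ("EUR", "EASN", "B"):
        if t >= model.t_ooa_split:
            return model.n_afr
        if pop == "B" or t >= model.t_eur_easn_split:
            return model.n_b
        if pop == "EUR":
            return model.n_eur0 * math.exp(model.r_eur * (model.t_eur_easn_split - t))
        return model.n_easn0 * math.exp(model.r_easn * (model.t_eur_easn_split - t))
    raise ValueError(f"unknown population {pop!r}")


@dataclass
class ThetaScaling:
    """theta = 4 N_e mu L bookkeeping for converting a fitted theta to N_e."""

    theta: float
    mu: float
    length: float

    def __post_init__(self):
        if min(self.theta, self.mu, self.length) <= 0:
            raise ValueError("theta, mu, and L must all be positive")

    @property
    def n_ref(self) -> float:
        return self.theta / (4.0 * self.mu * self.length)


def reference_ne(ts: ThetaScaling) -> float:
    """Reference effective size from theta = 4 N_e mu L."""
    return ts.n_ref


def rescale(model: ThreePopModel, q: float) -> ThreePopModel:
    """Rescale for desk-scale forward simulation.

    Sizes and times divide by ``q``; per-generation migration and growth
    rates multiply by ``q``. Paired with multiplying mu, r, and s by ``q``
    in the simulation configuration, the coalescent-scale compound
    parameters (theta, rho, 2Ns, 4Nm) are invariant.
    """
    if q <= 0:
        raise ValueError("rescale factor must be positive")
    return replace(
        model,
        n_anc=model.n_anc / q,
        n_afr=model.n_afr / q,
        t_expansion=model.t_expansion / q,
        n_b=model.n_b / q,
        t_ooa_split=model.t_ooa_split / q,
        m_afr_b=model.m_afr_b * q,
        n_eur0=model.n_eur0 / q,
        r_eur=model.r_eur * q,
        n_easn0=model.n_easn0 / q,
        r_easn=model.r_easn * q,
        t_eur_easn_split=model.t_eur_easn_split / q,
        m_afr_eur=model.m_afr_eur * q,
        m_afr_easn=model.m_afr_easn * q,
        m_eur_easn=model.m_eur_easn * q,
    )


def validate(model: ThreePopModel) -> list[str]:
    """Invariant checks; returns a list of diagnostics (empty when valid)."""
    diags = []
    for name in ("n_anc", "n_afr", "n_b", "n_eur0", "n_easn0"):
        if getattr(model, name) <= 0:
            diags.append(f"{name} must be positive")
    if not model.t_expansion > model.t_ooa_split > model.t_eur_easn_split > 0:
        diags.append(
            "times must satisfy t_expansion > t_ooa_split > t_eur_easn_split > 0"
        )
    for name in ("m_afr_b", "m_afr_eur", "m_afr_easn", "m_eur_easn"):
        if getattr(model, name) < 0:
            diags.append(f"{name} must be non-negative")
    if model.m_afr_eur + model.m_afr_easn >= 1 or model.m_afr_b >= 1:
        diags.append("per-generation migration fractions must sum below 1")
    if model.generation_time <= 0:
        diags.append("generation time must be positive")
    return diags


def size_trajectory(
    model: ThreePopModel, step: float = 100.0, pops=("AFR", "EUR", "EASN")
) -> pd.DataFrame:
    """Size-vs-time table (for trajectory plots / TSV export)."""
    times = np.arange(0.0, model.t_total + step, step)
    rows = []
    for t in times[::-1]:
        row = {"generations_ago": t, "years_ago": t * model.generation_time}
        for pop in pops:
            row[f"N_{pop}"] = size_at(model, pop, t)
        rows.append(row)
    return pd.DataFrame(rows)


def load_model(path) -> ThreePopModel:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return ThreePopModel(**data)


def save_model(model: ThreePopModel, path):
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(model), fh, sort_keys=False)
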