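"""Model parameters and named presets.

All rates are per day; the biomass "unit" is abstract (the model never
pins it to grams or stems) and every biomass quantity is reported in that
same unit.  The handling time ``h`` has units of days per biomass unit
per larva and is the parameter the rest of the package sweeps.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

#: Field names every flat configuration must provide.
REQUIRED_KEYS = (
    "tau_p", "tau_s", "k_l", "m", "P", "q", "mu_a",
    "mu_s", "e", "sigma", "h", "k_s", "k_r", "mu_r",
)

#: Keys a config may carry in addition to the 14 rate constants.
SCENARIO_KEYS = ("A0", "R0", "S_init", "L_init", "t_end", "step", "h_offset")


@dataclass(frozen=True)
class ModelParameters:
    """Rate constants, delays and functional-form constants of the model.

    Attributes
    ----------
    tau_p : float
        Egg-to-adult maturation delay of the psyllid, days.
    tau_s : float
        Life-span of a knotweed stem, days.
    k_l : float
        Excess larval mortality scale when sap is scarce, per day.
    m : float
        Asymptotic (sap-plentiful) larval mortality, per day.
    P : float
        Maximal per-adult egg-laying rate, eggs/adult/day.
    q : float
        Crowdedness constant of the Ricker birth law (dimensionless).
    mu_a : float
        Adult per-capita mortality, per day.
    mu_s : float
        Natural per-capita loss of stem biomass, per day.
    e : float
        Sap encounter rate, per larva per day per biomass unit.
    sigma : float
        Ingested fraction of encountered biomass, in (0, 1].
    h : float
        Handling (digestion) time, days per biomass unit per larva.
    k_s : float
        Stem production coefficient, b_s(R) = k_s R, per day.
    k_r : float
        Rhizome production coefficient, b_r(S) = k_r S, per day.
    mu_r : float
        Rhizome per-capita loss, per day.
    """

    tau_p: float
    tau_s: float
    k_l: float
    m: float
    P: float
    q: float
    mu_a: float
    mu_s: float
    e: float
    sigma: float
    h: float
    k_s: float
    k_r: float
    mu_r: float

    def __post_init__(self) -> None:
        problems = []
        for name in REQUIRED_KEYS:
            value = getattr(self, name)
            if not isinstance(value, (int, float)):
                problems.append(f"{name} must be numeric, got {value!r}")
            elif name == "h":
                if value < 0:
                    problems.append(f"h must be >= 0, got {value}")
            elif value <= 0:
                problems.append(f"{name} must be > 0, got {value}")
        if isinstance(self.sigma, (int, float)) and self.sigma > 1:
            problems.append(f"sigma is an ingested fraction and must be <= 1, got {self.sigma}")
        if problems:
            raise ValueError("invalid parameters: " + "; ".join(problems))

    @property
    def mu_l0(self) -> float:
        """Larval mortality with no stems at all, mu_l(0) = k_l + m."""
        return self.k_l + self.m

    def replace(self, **changes) -> "ModelParameters":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return {name: getattr(self, name) for name in REQUIRED_KEYS}


# m = 0.0205 per day is the sap-plentiful larval mortality; k_l = 1 - m
# normalises mu_l(0) to exactly 1 per day.  The two presets differ only in
# the fecundity P: the simulation studies use P = 16.9867, the parameter
# table also quotes the raw experimental estimate P = 23.9798.  Both ship;
# they are not reconciled.
_EQ52 = dict(
    tau_p=32.2, tau_s=150.0,
    m=0.0205, k_l=1.0 - 0.0205,
    P=16.9867, q=1.0, mu_a=0.0806,
    mu_s=0.01, e=1.0, sigma=1.0, h=1.0,
    k_s=0.1, k_r=0.1, mu_r=0.01,
)

PARAMETER_PRESETS: dict[str, dict] = {
    "table1_eq52": dict(_EQ52),
    "table1": dict(_EQ52, P=23.9798),
}


def preset(name: str = "table1_eq52") -> ModelParameters:
    """Return a named parameter preset as a :class:`ModelParameters`."""
    try:
        return ModelParameters(**PARAMETER_PRESETS[name])
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PARAMETER_PRESETS)}"
        ) from None


def load_params(path: str | Path) -> tuple[ModelParameters, dict]:
    """Read a flat YAML/JSON config into parameters plus scenario fields.

    The file must contain exactly the 14 rate-constant keys (see
    ``REQUIRED_KEYS``); it may additionally contain scenario keys such as
    ``A0``, ``R0``, ``t_end``.  Unknown keys are rejected by name so typos
    never silently fall back to defaults.

    Returns
    -------
    (ModelParameters, dict)
        The validated parameters and the (possibly empty) scenario fields.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".json",):
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a flat mapping")

    missing = [k for k in REQUIRED_KEYS if k not in raw]
    if missing:
        raise ValueError(f"{path}: missing required keys: {missing}")
    unknown = [k for k in raw if k not in REQUIRED_KEYS + SCENARIO_KEYS]
    if unknown:
        raise ValueError(f"{path}: unknown keys: {unknown}")

    params = ModelParameters(**{k: float(raw[k]) for k in REQUIRED_KEYS})
    scenario = {k: float(raw[k]) for k in SCENARIO_KEYS if k in raw}
    return params, scenario


def dump_params(params: ModelParameters, path: str | Path, **scenario) -> None:
    """Write parameters (plus optional scenario fields) as flat YAML."""
    payload = params.to_dict()
    payload.update(scenario)
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))
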