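"""Model parameters, network topology and configuration loading.

All numeric constants of the model live in a YAML parameter file (the
packaged default is ``stngpe/data/default_params.yaml``); the dataclasses
here are typed views of that file.  Units: time in ms, potentials in mV,
conductances/currents in the model's nominal units.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Literal

import numpy as np
import yaml

CellClass = Literal["STN", "GPe"]


@dataclass(frozen=True)
class NeuronParameters:
    """Parameters of one conductance-based model cell (STN or GPe).

    STN and GPe cells share the same equations and differ only in these
    values.  Gating curves follow the conventions documented in the
    default parameter file: sigmoidal steady states ``x_inf(v)`` with
    midpoint ``theta_x`` and slope ``sigma_x``, voltage-dependent time
    constants ``tau_x(v)``, and the sigmoid-difference T-current gate
    ``b_inf(r)``.
    """

    cell_class: CellClass
    C: float
    g_Na: float
    g_K: float
    g_L: float
    g_Ca: float
    g_T: float
    g_AHP: float
    v_Na: float
    v_K: float
    v_L: float
    v_Ca: float
    v_AHP: float
    k1: float
    epsilon: float
    k_Ca: float
    phi_n: float
    phi_h: float
    phi_r: float
    theta_m: float
    sigma_m: float
    theta_h: float
    sigma_h: float
    theta_n: float
    sigma_n: float
    theta_r: float
    sigma_r: float
    theta_a: float
    sigma_a: float
    theta_s: float
    sigma_s: float
    theta_b: float
    sigma_b: float
    tau_n0: float
    tau_n1: float
    theta_tau_n: float
    sigma_tau_n: float
    tau_h0: float
    tau_h1: float
    theta_tau_h: float
    sigma_tau_h: float
    tau_r0: float
    tau_r1: float
    theta_tau_r: float
    sigma_tau_r: float
    I_app: float
    i_app_jitter: float = 0.0

    def __post_init__(self) -> None:
        if self.i_app_jitter < 0:
            raise ValueError("i_app_jitter must be >= 0")
        for name in ("g_Na", "g_K", "g_L", "g_Ca", "g_T", "g_AHP"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.C <= 0:
            raise ValueError("C must be > 0")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.k1 <= 0:
            raise ValueError("k1 must be > 0")
        if self.cell_class not in ("STN", "GPe"):
            raise ValueError(f"unknown cell_class {self.cell_class!r}")

    def pack(self) -> np.ndarray:
        """Pack into a flat float64 array in :data:`PARAM_ORDER` order."""
        return np.array([getattr(self, name) for name in PARAM_ORDER], dtype=np.float64)


#: Field order used by the packed-array representation consumed by the
#: integration kernel.  Index constants in :mod:`stngpe._kernels` mirror it.
PARAM_ORDER: tuple[str, ...] = tuple(
    f.name for f in dataclasses.fields(NeuronParameters) if f.name != "cell_class"
)


@dataclass(frozen=True)
class SynapseParameters:
    """First-order kinetic synapse: ds/dt = alpha*H(v_pre - theta_g)*(1-s) - beta*s."""

    alpha: float
    beta: float
    theta_g: float
    Theta_gH: float
    sigma_gH: float
    g_syn: float
    v_syn: float
    polarity: Literal["excitatory", "inhibitory"]

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be > 0")
        if self.sigma_gH == 0:
            raise ValueError("sigma_gH must be nonzero")
        if self.polarity not in ("excitatory", "inhibitory"):
            raise ValueError(f"unknown polarity {self.polarity!r}")

    def pack(self) -> np.ndarray:
        return np.array(
            [self.alpha, self.beta, self.theta_g, self.Theta_gH, self.sigma_gH,
             self.g_syn, self.v_syn],
            dtype=np.float64,
        )


SYN_PARAM_ORDER: tuple[str, ...] = (
    "alpha", "beta", "theta_g", "Theta_gH", "sigma_gH", "g_syn", "v_syn",
)


@dataclass(frozen=True)
class NetworkTopology:
    """Ring topology: STN i -> GPe i; GPe i -> STN i-1, i, i+1 (circular).

    Adjacency matrices are exposed as dense 0/1 arrays with rows indexed
    by the postsynaptic neuron.
    """

    n_stn: int = 10
    n_gpe: int = 10

    def __post_init__(self) -> None:
        if self.n_stn != self.n_gpe:
            raise ValueError("ring topology requires n_stn == n_gpe")
        if self.n_stn < 3:
            raise ValueError("ring topology requires at least 3 neurons per population")

    @property
    def stn_to_gpe(self) -> np.ndarray:
        """(n_gpe, n_stn) adjacency: GPe i receives from STN i."""
        return np.eye(self.n_gpe, self.n_stn)

    @property
    def gpe_to_stn(self) -> np.ndarray:
        """(n_stn, n_gpe) adjacency: STN i receives from GPe i-1, i, i+1."""
        n = self.n_stn
        a = np.zeros((n, self.n_gpe))
        idx = np.arange(n)
        for shift in (-1, 0, 1):
            a[idx, (idx + shift) % n] = 1.0
        return a


@dataclass(frozen=True)
class SimulationSettings:
    dt: float = 0.05
    duration: float = 20000.0
    transient: float = 1000.0
    spike_threshold: float = -20.0
    spike_refractory: float = 2.0
    v_init_low: float = -65.0
    v_init_high: float = -55.0
    ca_init: float = 0.3
    s_init: float = 0.0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.duration <= self.transient:
            raise ValueError("duration must exceed transient")


@dataclass(frozen=True)
class AnalysisSettings:
    beta_band: tuple[float, float] = (10.0, 30.0)
    filter_order: int = 4
    slow_variable: Literal["r", "Ca", "s"] = "r"
    pca_threshold: float = 0.8
    lfp_neighborhood: int = 1


@dataclass(frozen=True)
class ModelConfig:
    """Complete model configuration: cells, synapses, topology, run settings."""

    stn: NeuronParameters
    gpe: NeuronParameters
    stn_to_gpe: SynapseParameters
    gpe_to_stn: SynapseParameters
    topology: NetworkTopology
    simulation: SimulationSettings = field(default_factory=SimulationSettings)
    analysis: AnalysisSettings = field(default_factory=AnalysisSettings)

    # -- construction -------------------------------------------------

    @classmethod
    def from_dict(cls, raw: dict) -> "ModelConfig":
        ana = dict(raw.get("analysis", {}))
        if "beta_band" in ana:
            ana["beta_band"] = tuple(float(x) for x in ana["beta_band"])
        return cls(
            stn=NeuronParameters(**raw["stn"]),
            gpe=NeuronParameters(**raw["gpe"]),
            stn_to_gpe=SynapseParameters(**raw["synapse"]["stn_to_gpe"]),
            gpe_to_stn=SynapseParameters(**raw["synapse"]["gpe_to_stn"]),
            topology=NetworkTopology(**raw.get("topology", {})),
            simulation=SimulationSettings(**raw.get("simulation", {})),
            analysis=AnalysisSettings(**ana),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "ModelConfig":
        text = resources.files("stngpe").joinpath("data/default_params.yaml").read_text()
        return cls.from_dict(yaml.safe_load(text))

    # -- convenience --------------------------------------------------

    def with_pair(self, g_syn: float, i_app_gpe: float) -> "ModelConfig":
        """Return a copy at a (g_syn, I_app) parameter pair.

        ``g_syn`` scales the pallido-subthalamic (GPe->STN) conductance;
        ``i_app_gpe`` is the constant current applied to GPe cells
        (average striato-pallidal effect).  STN cells keep their own
        fixed applied current.
        """
        return replace(
            self,
            gpe_to_stn=replace(self.gpe_to_stn, g_syn=float(g_syn)),
            gpe=replace(self.gpe, I_app=float(i_app_gpe)),
        )

    def with_simulation(self, **kw) -> "ModelConfig":
        return replace(self, simulation=replace(self.simulation, **kw))

    def to_dict(self) -> dict:
        return {
            "stn": dataclasses.asdict(self.stn),
            "gpe": dataclasses.asdict(self.gpe),
            "synapse": {
                "stn_to_gpe": dataclasses.asdict(self.stn_to_gpe),
                "gpe_to_stn": dataclasses.asdict(self.gpe_to_stn),
            },
            "topology": dataclasses.asdict(self.topology),
            "simulation": dataclasses.asdict(self.simulation),
            "analysis": {
                **dataclasses.asdict(self.analysis),
                "beta_band": list(self.analysis.beta_band),
            },
        }

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def digest(self) -> str:
        """Short stable hash of the full configuration (for run manifests)."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
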