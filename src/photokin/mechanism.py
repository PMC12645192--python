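"""Mass-action simulation of riboflavin-sensitized photodegradation.

The reaction network encodes the photosensitization scheme for donepezil
(DPZ) degradation by riboflavin (RF): direct excitation and intersystem
crossing of RF, type I electron transfer (RF triplet + DPZ -> radical
pair), type II energy transfer (RF triplet + triplet oxygen -> singlet
oxygen, which oxidizes DPZ), and the anaerobic ground-state-complex route
(complex excitation, H-abstraction to the semiquinone RFH*, semiquinone
disproportionation to oxidized and fully reduced flavin, and reoxidation of
the reduced flavin by trace oxygen).

Photon absorption is modeled as a pseudo-first-order excitation channel
(ground chromophore -> excited singlet at rate k_exc) rather than explicit
radiation transport; k_exc is derived from lamp flux x absorbed fraction /
(volume x Avogadro x concentration), consistent with the quantum-yield
module. No experimental rate constants exist for the elementary steps;
the defaults in ``data/default_rates.yaml`` are order-of-magnitude
literature-scale placeholders (triplet decay from the microsecond triplet
lifetimes), so every quantitative claim about the simulator is a property
(conservation, log-linearity, monotonicity, rate ratios), never a value.

Units: min^-1 for first-order steps, M^-1 min^-1 for second-order steps.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import yaml
from scipy.integrate import solve_ivp

from .kinetics import AVOGADRO, FirstOrderFit, fit_first_order
from .spectra import AbsorbanceSpectrum, LampSpectrum
from . import kinetics as _kinetics

__all__ = [
    "SPECIES",
    "FLAVIN_SPECIES",
    "DPZ_SPECIES",
    "Reaction",
    "ReactionScheme",
    "SimulationResult",
    "KobsEstimate",
    "IntegrationError",
    "default_rates",
    "excitation_rate",
    "preset_scheme",
    "integrate",
    "effective_k_obs",
    "scan_rf",
    "scheme_to_yaml",
    "scheme_from_yaml",
]

#: The closed species set of the reaction network.
SPECIES = (
    "DPZ",
    "DPZ_cat_radical",
    "DPZ_radical",
    "RF_ground",
    "RF_singlet",
    "RF_triplet",
    "RF_anion_radical",
    "RFH_radical",
    "RFH2",
    "RFH2_cat_radical",
    "RF_ox",
    "complex_ground",
    "complex_singlet",
    "complex_triplet",
    "O2_triplet",
    "O2_singlet",
    "superoxide",
    "H2O2",
    "products",
)

#: Species carrying one flavin moiety (conserved chromophore count).
FLAVIN_SPECIES = frozenset(
    {
        "RF_ground",
        "RF_singlet",
        "RF_triplet",
        "RF_anion_radical",
        "RFH_radical",
        "RFH2",
        "RFH2_cat_radical",
        "RF_ox",
        "complex_ground",
        "complex_singlet",
        "complex_triplet",
    }
)

#: Species carrying one DPZ-derived moiety ("products" is the DPZ sink).
DPZ_SPECIES = frozenset(
    {
        "DPZ",
        "DPZ_cat_radical",
        "DPZ_radical",
        "products",
        "complex_ground",
        "complex_singlet",
        "complex_triplet",
    }
)

#: Air-saturated dissolved oxygen at 25 C, M (continuous bubbling).
O2_SATURATION_M = 2.5e-4
#: Residual trace oxygen used for anaerobic runs (1% of saturation).
O2_TRACE_M = 2.5e-6

PRESETS = ("typeI_aerobic", "typeII_aerobic", "anaerobic_complex", "combined_aerobic")


class IntegrationError(RuntimeError):
    """Solver failure; carries the last accepted state."""

    def __init__(self, message: str, last_time: float, last_state: dict[str, float]):
        super().__init__(message)
        self.last_time = last_time
        self.last_state = last_state


@dataclass(frozen=True)
class Reaction:
    """One mass-action step of total order 1 or 2.

    ``label`` is the equation number of the step in the published scheme
    (deactivation steps carry descriptive labels instead).
    """

    reactants: tuple[str, ...]
    products: tuple[str, ...]
    rate_constant: float
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.reactants) not in (1, 2):
            raise ValueError("total reactant order must be 1 or 2")
        if self.rate_constant < 0:
            raise ValueError("rate constant must be nonnegative")
        unknown = [s for s in (*self.reactants, *self.products) if s not in SPECIES]
        if unknown:
            raise ValueError(f"unknown species {unknown}")


@dataclass
class ReactionScheme:
    """Species, reactions and excitation channels of one simulated condition."""

    name: str
    reactions: list[Reaction]
    excitation: dict[str, float] = field(default_factory=dict)  # chromophore -> k_exc, min^-1
    buffered: frozenset[str] = frozenset()  # species held constant (e.g. bubbled O2)
    species: tuple[str, ...] = SPECIES

    def __post_init__(self) -> None:
        for r in self.reactions:
            for s in (*r.reactants, *r.products):
                if s not in self.species:
                    raise ValueError(f"reaction {r.label} references undeclared species {s}")

    def moiety_audit(self) -> None:
        """Check flavin and DPZ moiety balance of every reaction."""
        for r in self.reactions:
            for pool, tag in ((FLAVIN_SPECIES, "flavin"), (DPZ_SPECIES, "DPZ")):
                lhs = sum(1 for s in r.reactants if s in pool)
                rhs = sum(1 for s in r.products if s in pool)
                if lhs != rhs:
                    raise ValueError(f"reaction {r.label or r} does not conserve the {tag} moiety")

    def hash(self) -> str:
        payload = repr(
            (
                self.name,
                sorted((r.reactants, r.products, r.rate_constant, r.label) for r in self.reactions),
                sorted(self.excitation.items()),
                sorted(self.buffered),
            )
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class SimulationResult:
    times: np.ndarray
    trajectories: dict[str, np.ndarray]  # species -> M
    scheme_hash: str
    diagnostics: dict


@dataclass(frozen=True)
class KobsEstimate:
    fit: FirstOrderFit | None
    low_signal: bool


def default_rates() -> dict[str, float]:
    """Elementary rate constants from the packaged configuration file."""
    text = resources.files("photokin.data").joinpath("default_rates.yaml").read_text()
    data = yaml.safe_load(text)
    return {k: float(v) for k, v in data.items()}


def excitation_rate(
    lamp: LampSpectrum,
    absorbance: AbsorbanceSpectrum,
    volume_l: float,
    conc: float,
) -> float:
    """Pseudo-first-order excitation rate of a chromophore, min^-1.

    Absorbed einstein min^-1 (lamp flux x overlap fraction / Avogadro)
    divided by the moles of chromophore in the irradiated volume.
    """
    if not (volume_l > 0 and conc > 0):
        raise ValueError("volume and concentration must be positive")
    f = _kinetics.absorbed_fraction(lamp, absorbance)
    einstein_per_min = lamp.photon_flux * 60.0 / AVOGADRO
    return einstein_per_min * f / (volume_l * conc)


def _excitation_steps(rates: dict[str, float], labels: tuple[str, str]) -> list[Reaction]:
    """Free-RF excitation, isc and excited-state deactivation."""
    return [
        Reaction(("RF_ground",), ("RF_singlet",), rates["k_exc_rf"], labels[0]),
        Reaction(("RF_singlet",), ("RF_triplet",), rates["k_isc"], labels[1]),
        Reaction(("RF_singlet",), ("RF_ground",), rates["k_singlet_decay"], "S1 decay"),
        Reaction(("RF_triplet",), ("RF_ground",), rates["k_triplet_decay"], "T1 decay"),
    ]


def preset_scheme(name: str, rates: dict[str, float] | None = None) -> ReactionScheme:
    """Build one of the named reaction schemes.

    * ``typeI_aerobic`` — electron transfer from the RF triplet to DPZ
      giving the radical pair, deprotonation, and oxygen capture of the DPZ
      radical (steps 7-11).
    * ``typeII_aerobic`` — energy transfer from the RF triplet to triplet
      oxygen giving singlet oxygen, which oxidizes DPZ (steps 12-15, plus
      the singlet-oxygen relaxation step 24).
    * ``combined_aerobic`` — union of the two aerobic pathways; oxygen is
      buffered at air saturation (continuous bubbling).
    * ``anaerobic_complex`` — ground-state RF...DPZ complex formation,
      complex excitation and H-abstraction to the semiquinone, semiquinone
      disproportionation, and reoxidation of reduced flavin by trace oxygen
      (steps 16-24). No oxygen-consuming DPZ oxidation occurs before step
      21.
    """
    r = default_rates()
    if rates:
        r.update(rates)

    if name == "typeI_aerobic":
        reactions = _excitation_steps(r, ("7", "8")) + [
            Reaction(("RF_triplet", "DPZ"), ("RF_anion_radical", "DPZ_cat_radical"), r["k_electron_transfer"], "9"),
            Reaction(("DPZ_cat_radical",), ("DPZ_radical",), r["k_deprotonation"], "10"),
            Reaction(("DPZ_radical", "O2_triplet"), ("products", "H2O2"), r["k_radical_oxygen"], "11"),
        ]
        buffered = frozenset({"O2_triplet"})
    elif name == "typeII_aerobic":
        reactions = _excitation_steps(r, ("12", "13")) + [
            Reaction(("RF_triplet", "O2_triplet"), ("RF_ground", "O2_singlet"), r["k_oxygen_quench"], "14"),
            Reaction(("DPZ", "O2_singlet"), ("products", "H2O2"), r["k_singlet_oxygen_attack"], "15"),
            Reaction(("O2_singlet",), ("O2_triplet",), r["k_singlet_oxygen_decay"], "24"),
        ]
        buffered = frozenset({"O2_triplet"})
    elif name == "combined_aerobic":
        reactions = _excitation_steps(r, ("7,12", "8,13")) + [
            Reaction(("RF_triplet", "DPZ"), ("RF_anion_radical", "DPZ_cat_radical"), r["k_electron_transfer"], "9"),
            Reaction(("DPZ_cat_radical",), ("DPZ_radical",), r["k_deprotonation"], "10"),
            Reaction(("DPZ_radical", "O2_triplet"), ("products", "H2O2"), r["k_radical_oxygen"], "11"),
            Reaction(("RF_triplet", "O2_triplet"), ("RF_ground", "O2_singlet"), r["k_oxygen_quench"], "14"),
            Reaction(("DPZ", "O2_singlet"), ("products", "H2O2"), r["k_singlet_oxygen_attack"], "15"),
            Reaction(("O2_singlet",), ("O2_triplet",), r["k_singlet_oxygen_decay"], "24"),
        ]
        buffered = frozenset({"O2_triplet"})
    elif name == "anaerobic_complex":
        reactions = [
            Reaction(("RF_ground", "DPZ"), ("complex_ground",), r["k_complex_formation"], "16"),
            Reaction(("complex_ground",), ("complex_singlet",), r["k_exc_complex"], "17"),
            Reaction(("complex_singlet",), ("complex_triplet",), r["k_isc"], "18"),
            Reaction(("complex_singlet",), ("complex_ground",), r["k_singlet_decay"], "S1 decay (complex)"),
            Reaction(("complex_triplet",), ("complex_ground",), r["k_triplet_decay"], "T1 decay (complex)"),
            Reaction(("complex_triplet",), ("RFH_radical", "products"), r["k_h_abstraction"], "19"),
            Reaction(("RFH_radical", "RFH_radical"), ("RF_ox", "RFH2"), r["k_disproportionation"], "20"),
            Reaction(("RFH2", "O2_triplet"), ("RFH2_cat_radical", "superoxide"), r["k_rfh2_oxidation"], "21"),
            Reaction(("RFH2_cat_radical", "superoxide"), ("RF_ground", "H2O2"), r["k_radical_recombination"], "22"),
            *_excitation_steps(r, ("7", "8")),
            Reaction(("RF_triplet", "O2_triplet"), ("RF_ground", "O2_singlet"), r["k_oxygen_quench"], "23"),
            Reaction(("O2_singlet",), ("O2_triplet",), r["k_singlet_oxygen_decay"], "24"),
        ]
        buffered = frozenset()
    else:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESETS}")

    excitation = {"RF": r["k_exc_rf"]}
    if name == "anaerobic_complex":
        excitation["complex"] = r["k_exc_complex"]
    scheme = ReactionScheme(name=name, reactions=reactions, excitation=excitation, buffered=buffered)
    scheme.moiety_audit()
    return scheme


def default_initial_concentrations(scheme: ReactionScheme, dpz0: float = 1.0e-4, rf0: float = 0.5e-4) -> dict[str, float]:
    """Study-condition initial state: DPZ 1.00e-4 M, RF 0.50e-4 M, oxygen per condition."""
    o2 = O2_TRACE_M if scheme.name == "anaerobic_complex" else O2_SATURATION_M
    return {"DPZ": dpz0, "RF_ground": rf0, "O2_triplet": o2}


def _build_arrays(scheme: ReactionScheme):
    index = {s: i for i, s in enumerate(scheme.species)}
    n_s, n_r = len(scheme.species), len(scheme.reactions)
    stoich = np.zeros((n_s, n_r))
    reactant_idx: list[tuple[int, ...]] = []
    rates = np.zeros(n_r)
    for j, rxn in enumerate(scheme.reactions):
        for s in rxn.reactants:
            stoich[index[s], j] -= 1
        for s in rxn.products:
            stoich[index[s], j] += 1
        reactant_idx.append(tuple(index[s] for s in rxn.reactants))
        rates[j] = rxn.rate_constant
    free = np.array([s not in scheme.buffered for s in scheme.species], dtype=bool)
    return index, stoich, reactant_idx, rates, free


def integrate(
    scheme: ReactionScheme,
    initial_concs: dict[str, float],
    times: Sequence[float],
    rel_tol: float = 1e-8,
    abs_tol: float | None = None,
) -> SimulationResult:
    """Integrate dC/dt = S v(C) with mass-action rates (stiff BDF solver).

    Buffered species are held constant (their net rate is zeroed), which is
    how continuously bubbled oxygen and pseudo-first-order sensitizer
    conditions are represented. An analytic Jacobian is supplied; the
    default absolute tolerance is scaled well below the smallest transient
    populations so moiety conservation holds to ~1e-8 relative.
    """
    times = np.asarray(times, dtype=float)
    if np.any(np.array(list(initial_concs.values())) < 0):
        raise ValueError("initial concentrations must be nonnegative")
    index, stoich, reactant_idx, k, free = _build_arrays(scheme)

    y0 = np.zeros(len(scheme.species))
    for s, c in initial_concs.items():
        if s not in index:
            raise ValueError(f"unknown species {s}")
        y0[index[s]] = c

    mask = free.astype(float)

    def rhs(_t, y):
        v = k.copy()
        for j, idxs in enumerate(reactant_idx):
            for i in idxs:
                v[j] *= y[i]
        return (stoich @ v) * mask

    def jac(_t, y):
        n_s = y.size
        jv = np.zeros((len(k), n_s))  # d v_j / d y_i
        for j, idxs in enumerate(reactant_idx):
            if len(idxs) == 1:
                jv[j, idxs[0]] += k[j]
            else:
                a, b = idxs
                jv[j, a] += k[j] * y[b]
                jv[j, b] += k[j] * y[a]
        return (stoich @ jv) * mask[:, None]

    if abs_tol is None:
        abs_tol = rel_tol * max(y0.max(), 1e-12) * 1e-10

    sol = solve_ivp(
        rhs,
        (float(times[0]), float(times[-1])),
        y0,
        method="BDF",
        t_eval=times,
        rtol=rel_tol,
        atol=abs_tol,
        jac=jac,
    )
    if not sol.success:
        last_state = {s: float(sol.y[index[s], -1]) for s in scheme.species} if sol.y.size else dict(initial_concs)
        raise IntegrationError(sol.message, float(sol.t[-1]) if sol.t.size else float(times[0]), last_state)

    trajectories = {s: sol.y[index[s]] for s in scheme.species}
    return SimulationResult(
        times=times,
        trajectories=trajectories,
        scheme_hash=scheme.hash(),
        diagnostics={"nfev": sol.nfev, "njev": sol.njev, "status": sol.status, "message": sol.message},
    )


def substrate_remaining(result: SimulationResult) -> np.ndarray:
    """Intact substrate: every DPZ-moiety species except the product sink.

    This is what the assay measures — ground-state complexation sequesters
    the substrate without degrading it, so complexed DPZ still counts as
    remaining.
    """
    total = np.zeros_like(result.times)
    for s in DPZ_SPECIES - {"products"}:
        total = total + result.trajectories[s]
    return total


def effective_k_obs(
    result: SimulationResult,
    species: str = "substrate",
    floor_fraction: float = 0.10,
) -> KobsEstimate:
    """Pseudo-first-order constant of substrate loss from a trajectory.

    ``species`` names one trajectory, or ``"substrate"`` for the intact
    substrate pool (free plus complexed DPZ; see
    :func:`substrate_remaining`). Fits ln C vs t over the window where the
    substrate stays at or above ``floor_fraction`` of its initial value.
    Less than 5% decay over that window raises the low-signal flag instead
    of returning a meaningless slope.
    """
    c = substrate_remaining(result) if species == "substrate" else result.trajectories[species]
    t = result.times
    c0 = c[0]
    if not c0 > 0:
        raise ValueError(f"{species} starts at zero")
    window = (c >= floor_fraction * c0) & (c > 0)
    t_w, c_w = t[window], c[window]
    if t_w.size < 3 or c_w[-1] > 0.95 * c0:
        if t_w.size >= 3:
            return KobsEstimate(fit_first_order(t_w, c_w), low_signal=True)
        return KobsEstimate(None, low_signal=True)
    return KobsEstimate(fit_first_order(t_w, c_w), low_signal=False)


def scan_rf(
    rf_concs: Sequence[float],
    preset: str = "combined_aerobic",
    dpz0: float = 1.0e-4,
    times: Sequence[float] | None = None,
    rates: dict[str, float] | None = None,
    rel_tol: float = 1e-8,
) -> list[tuple[float, float]]:
    """k_obs at each sensitizer concentration (one integration per point).

    Runs the preset scheme as-is (aerobic presets keep oxygen buffered at
    saturation) and fits the intact-substrate decay; the emergent k_obs
    grows with the sensitizer concentration, mirroring the catalytic role
    of the sensitizer. Deterministic given the scheme and tolerances. A
    zero-sensitizer point yields (essentially) no decay and reports
    k_obs = 0 via the low-signal path.
    """
    rf_concs = list(rf_concs)
    if len(rf_concs) < 2:
        raise ValueError("need at least two sensitizer concentrations")
    if times is None:
        times = np.linspace(0.0, 120.0, 61)
    out = []
    for rf0 in rf_concs:
        scheme = preset_scheme(preset, rates=rates)
        init = default_initial_concentrations(scheme, dpz0=dpz0, rf0=rf0)
        res = integrate(scheme, init, times, rel_tol=rel_tol)
        est = effective_k_obs(res)
        out.append((rf0, est.fit.k_obs if est.fit is not None else 0.0))
    return out


def scheme_to_yaml(scheme: ReactionScheme) -> str:
    """Serialize a scheme (species, reactions, constants, labels) to YAML."""
    doc = {
        "name": scheme.name,
        "species": list(scheme.species),
        "buffered": sorted(scheme.buffered),
        "excitation": dict(scheme.excitation),
        "reactions": [
            {
                "label": r.label,
                "reactants": list(r.reactants),
                "products": list(r.products),
                "rate_constant": r.rate_constant,
            }
            for r in scheme.reactions
        ],
    }
    return yaml.safe_dump(doc, sort_keys=False)


def scheme_from_yaml(text: str) -> ReactionScheme:
    doc = yaml.safe_load(text)
    reactions = [
        Reaction(
            tuple(r["reactants"]),
            tuple(r["products"]),
            float(r["rate_constant"]),
            str(r.get("label", "")),
        )
        for r in doc["reactions"]
    ]
    return ReactionScheme(
        name=doc.get("name", "custom"),
        reactions=reactions,
        excitation={k: float(v) for k, v in doc.get("excitation", {}).items()},
        buffered=frozenset(doc.get("buffered", [])),
        species=tuple(doc.get("species", SPECIES)),
    )
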