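"""Synthetic LC-MS and activity data with a ground-truth manifest.

The generator emulates the statistical structure of a plasma incubation
experiment — not plasma chemistry.  A free thiol peptide disappears by
first-order degradation plus first-order conversion into covalent pools
(an albumin-fragment disulfide conjugate and LMW thiol adducts), each pool
with its own degradation rate; the two-compartment system has a closed
form, so no ODE solver is involved.  Each species elutes as a Gaussian
peak whose isotope cluster follows the theoretical pattern, with ppm
jitter, multiplicative log-normal intensity noise and decoy peaks placed
at least 50 ppm from every true signal.  Antibody-competition tables come
from a 4PL response at a drifting true IC50.

Every randomized output is a pure function of (scenario, seed): no hidden
global random state.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .conjugates import SpeciesCandidate
from .masses import PeptideSpecies, adduct_delta
from .quantify import DEFAULT_CHARGES, isotope_pattern

__all__ = [
    "BoundPool",
    "SimulationScenario",
    "GroundTruthManifest",
    "simulate_species_kinetics",
    "emit_peaklists",
    "ground_truth",
    "simulate_activity_tables",
    "simulate_decay_series",
    "activity_trajectory",
    "scenario_to_config",
    "scenario_from_config",
    "PLASMA_MS_SAMPLING_GRID",
    "LMW_TIMEPOINT_GRID",
]

#: Plasma-incubation sampling grid of the MS stability assay (minutes).
PLASMA_MS_SAMPLING_GRID = (0.0, 5.0, 10.0, 20.0, 30.0, 45.0, 60.0, 90.0, 120.0)
#: Denser early grid used when following fast-interconverting LMW species.
LMW_TIMEPOINT_GRID = (0.0, 2.5, 5.0, 10.0, 15.0, 20.0, 30.0, 60.0, 120.0)


@dataclass(frozen=True)
class BoundPool:
    """One covalent product pool fed by the free peptide.

    ``kind`` is ``"crosslink"`` (disulfide conjugate with the carrier
    fragment) or the name of a thiol adduct in the built-in library.
    ``fraction`` is this pool's share of the total conversion flux;
    ``degradation_half_life`` of ``None`` means the pool is stable on the
    observation window.
    """

    name: str
    kind: str
    fraction: float
    degradation_half_life: Optional[float] = None
    initial_fraction: float = 0.0


@dataclass(frozen=True)
class SimulationScenario:
    """Full parameterization of one synthetic plasma-incubation experiment.

    Defaults reproduce the study conditions for the JM#21-like analyte: the
    free pool disappears with a net half-life of 1.7 min (degradation and
    conversion contributing equally), the covalent pools are stable over
    the 2 h window, sampling follows the 0–120 min grid, intensities carry
    10% log-normal noise and m/z values 3 ppm jitter.
    """

    analyte_sequence: str = "ILRWSRKLPCVS"
    analyte_label: str = "JM#21"
    carrier_fragment: str = "ALVLIAFAQYLQQCPFEDHVK"
    sampling_times: tuple = PLASMA_MS_SAMPLING_GRID
    free_degradation_half_life: float = 3.4  # min
    conversion_half_time: float = 3.4  # min; net free t1/2 = 1.7 min
    free_initial_fraction: float = 1.0
    bound_pools: tuple = (
        BoundPool("albumin-conjugate", "crosslink", 0.7, None),
        BoundPool("Cys-adduct", "Cys", 0.3, None),
    )
    # peak-list emission
    base_intensity: float = 1.0e6
    intensity_cv: float = 0.10
    mz_jitter_ppm: float = 3.0
    baseline_intensity: float = 0.0
    decoys_per_run: int = 100
    base_apex_min: float = 10.0
    apex_step_min: float = 3.0
    peak_sigma_min: float = 0.08
    scan_interval_min: float = 0.02
    intensity_floor: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.free_degradation_half_life is not None and self.free_degradation_half_life <= 0:
            raise ValueError("free_degradation_half_life must be positive")
        if self.conversion_half_time is not None and self.conversion_half_time <= 0:
            raise ValueError("conversion_half_time must be positive")
        fractions = sum(p.fraction for p in self.bound_pools)
        if fractions > 1.0 + 1e-9:
            raise ValueError(f"bound-pool fractions sum to {fractions} > 1")
        initial = self.free_initial_fraction + sum(p.initial_fraction for p in self.bound_pools)
        if initial > 1.0 + 1e-9:
            raise ValueError(f"initial fractions sum to {initial} > 1")
        for p in self.bound_pools:
            if p.degradation_half_life is not None and p.degradation_half_life <= 0:
                raise ValueError(f"pool {p.name}: degradation_half_life must be positive")

    # --- derived quantities ----------------------------------------------
    @property
    def k_degradation(self) -> float:
        hl = self.free_degradation_half_life
        return 0.0 if hl is None else math.log(2.0) / hl

    @property
    def k_conversion(self) -> float:
        ht = self.conversion_half_time
        return 0.0 if ht is None else math.log(2.0) / ht

    @property
    def net_free_half_life(self) -> float:
        """Apparent half-life of free-peptide disappearance, minutes."""
        k = self.k_degradation + self.k_conversion
        return math.inf if k == 0 else math.log(2.0) / k

    def candidates(self) -> dict[str, SpeciesCandidate]:
        """Species candidates keyed by pool name ('free' + bound pools)."""
        analyte = PeptideSpecies(self.analyte_sequence, label=self.analyte_label)
        out = {"free": SpeciesCandidate(analyte, "free",
                                        provenance=(f"analyte:{self.analyte_sequence}",))}
        for pool in self.bound_pools:
            if pool.kind == "crosslink":
                species = PeptideSpecies(self.carrier_fragment, disulfide_partner=analyte)
                cls = "crosslink"
                prov = (f"carrier:{self.carrier_fragment}",
                        f"analyte:{self.analyte_sequence}")
            else:
                species = PeptideSpecies(self.analyte_sequence,
                                         adduct=adduct_delta(pool.kind))
                cls = "adduct"
                prov = (f"analyte:{self.analyte_sequence}", f"adduct:{pool.kind}")
            out[pool.name] = SpeciesCandidate(species, cls, provenance=prov)
        return out


def _pool_rate(pool: BoundPool) -> float:
    return 0.0 if pool.degradation_half_life is None else math.log(2.0) / pool.degradation_half_life


def simulate_species_kinetics(scenario: SimulationScenario) -> pd.DataFrame:
    """Closed-form two-compartment abundances at the sampling times.

    Free pool: ``F(t) = F0·exp(−(kd+kc)·t)``.  Bound pool i fed at rate
    ``kc·f_i``:
    ``B_i(t) = B0_i·e^{−kb_i t} + kc_i F0 (e^{−kb_i t} − e^{−k_tot t})/(k_tot − kb_i)``
    with the ``kb_i → k_tot`` limit handled analytically.  Columns:
    time_min, species (pool name), abundance.
    """
    t = np.asarray(scenario.sampling_times, dtype=float)
    k_tot = scenario.k_degradation + scenario.k_conversion
    f0 = scenario.free_initial_fraction
    rows = [
        {"time_min": ti, "species": "free", "abundance": f0 * math.exp(-k_tot * ti)}
        for ti in t
    ]
    for pool in scenario.bound_pools:
        k_in = scenario.k_conversion * pool.fraction
        k_b = _pool_rate(pool)
        for ti in t:
            seeded = pool.initial_fraction * math.exp(-k_b * ti)
            if abs(k_tot - k_b) < 1e-12:
                fed = k_in * f0 * ti * math.exp(-k_tot * ti)
            else:
                fed = k_in * f0 * (math.exp(-k_b * ti) - math.exp(-k_tot * ti)) / (k_tot - k_b)
            rows.append({"time_min": ti, "species": pool.name, "abundance": seeded + fed})
    return pd.DataFrame(rows)


def _target_mzs(scenario: SimulationScenario) -> dict[str, list]:
    """Isotope patterns per pool and charge, computed once."""
    patterns: dict[str, list] = {}
    for name, cand in scenario.candidates().items():
        formula = cand.species.formula()
        zs = DEFAULT_CHARGES.get(cand.species_class, (1, 2, 3))
        patterns[name] = [isotope_pattern(formula, z, prune_below=1e-3) for z in zs]
    return patterns


def _apexes(scenario: SimulationScenario) -> dict[str, float]:
    names = ["free"] + [p.name for p in scenario.bound_pools]
    return {n: scenario.base_apex_min + i * scenario.apex_step_min
            for i, n in enumerate(names)}


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Multiplicative noise with mean 1 and coefficient of variation `cv`."""
    if cv <= 0:
        return 1.0 if size is None else np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def emit_peaklists(
    abundances: pd.DataFrame,
    scenario: SimulationScenario,
    seed: Optional[int] = None,
) -> list[tuple[float, pd.DataFrame]]:
    """Centroided peak lists (rt_min, mz, intensity) per sampling time.

    Peak-list ion current is proportional to pool abundance within the
    scenario's noise; decoy peaks never come within 50 ppm of a true
    isotope m/z.  Byte-reproducible for a fixed (scenario, seed).
    """
    seed = scenario.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    patterns = _target_mzs(scenario)
    apexes = _apexes(scenario)
    all_true_mz = np.concatenate(
        [p.mz_values for plist in patterns.values() for p in plist]
    )
    rt_lo = min(apexes.values()) - 1.0
    rt_hi = max(apexes.values()) + 1.0
    scans = np.arange(rt_lo, rt_hi + scenario.scan_interval_min / 2,
                      scenario.scan_interval_min)
    sigma = scenario.peak_sigma_min

    manifest = []
    for time, sub in abundances.groupby("time_min", sort=True):
        rows = []
        for _, rec in sub.iterrows():
            name, abundance = rec["species"], rec["abundance"]
            if abundance <= 0:
                continue
            apex = apexes[name]
            # wide support: the intensity floor, not the window edge, ends
            # the peak, so XIC interpolation across scan gaps stays unbiased
            support = (scans >= apex - 8 * sigma) & (scans <= apex + 8 * sigma)
            rts = scans[support]
            profile = np.exp(-0.5 * ((rts - apex) / sigma) ** 2)
            amplitude = scenario.base_intensity * abundance
            for pattern in patterns[name]:
                for mz_i, ab_i in zip(pattern.mz_values, pattern.abundances):
                    inten = amplitude * ab_i * profile
                    inten = inten * _lognormal_factor(rng, scenario.intensity_cv, len(inten))
                    jitter = rng.normal(0.0, scenario.mz_jitter_ppm, len(inten)) * 1e-6
                    keep = inten > scenario.intensity_floor
                    if not keep.any():
                        continue
                    rows.append(pd.DataFrame({
                        "rt_min": rts[keep],
                        "mz": mz_i * (1.0 + jitter[keep]),
                        "intensity": inten[keep] + scenario.baseline_intensity,
                    }))
        # decoys: uniform in m/z range, rejected within 50 ppm of any target
        n_decoys = scenario.decoys_per_run
        if n_decoys > 0:
            lo, hi = all_true_mz.min() * 0.9, all_true_mz.max() * 1.1
            decoy_mz = []
            while len(decoy_mz) < n_decoys:
                cand = rng.uniform(lo, hi, n_decoys)
                ok = np.all(
                    np.abs(cand[:, None] - all_true_mz[None, :])
                    / all_true_mz[None, :] * 1e6 >= 50.0,
                    axis=1,
                )
                decoy_mz.extend(cand[ok].tolist())
            decoy_mz = np.array(decoy_mz[:n_decoys])
            rows.append(pd.DataFrame({
                "rt_min": rng.uniform(rt_lo, rt_hi, n_decoys),
                "mz": decoy_mz,
                "intensity": 1e4 * _lognormal_factor(rng, 1.0, n_decoys),
            }))
        peaks = (
            pd.concat(rows, ignore_index=True)
            if rows else pd.DataFrame(columns=["rt_min", "mz", "intensity"])
        )
        peaks = peaks.sort_values(["rt_min", "mz"], kind="mergesort").reset_index(drop=True)
        manifest.append((float(time), peaks))
    return manifest


@dataclass
class GroundTruthManifest:
    """Everything needed to score a pipeline run against the generator."""

    scenario: SimulationScenario
    table: pd.DataFrame  # time_min, species, abundance, true_area
    true_half_lives: dict

    def to_json(self, path=None) -> str:
        payload = {
            "scenario": _scenario_dict(self.scenario),
            "table": self.table.to_dict(orient="records"),
            "true_half_lives": self.true_half_lives,
        }
        text = json.dumps(payload, indent=2, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def ground_truth(
    scenario: SimulationScenario, abundances: Optional[pd.DataFrame] = None
) -> GroundTruthManifest:
    """True abundances, noise-free XIC areas and generating half-lives.

    The true integrated area of a species at a timepoint is the analytic
    Gaussian area of its most intense isotopologue summed over charge
    states — exactly what the quantification stage estimates.
    """
    if abundances is None:
        abundances = simulate_species_kinetics(scenario)
    patterns = _target_mzs(scenario)
    gauss_area = scenario.peak_sigma_min * math.sqrt(2.0 * math.pi)
    area_factor = {
        name: sum(p.abundances.max() for p in plist) * scenario.base_intensity * gauss_area
        for name, plist in patterns.items()
    }
    table = abundances.copy()
    table["true_area"] = [
        area_factor[s] * a for s, a in zip(table["species"], table["abundance"])
    ]
    half_lives = {"free": scenario.net_free_half_life}
    for pool in scenario.bound_pools:
        half_lives[pool.name] = (
            pool.degradation_half_life if pool.degradation_half_life is not None else None
        )
    return GroundTruthManifest(scenario=scenario, table=table, true_half_lives=half_lives)


# --- activity / decay series ---------------------------------------------

def activity_trajectory(
    times: Sequence[float],
    half_life: float,
    plateau_pct: float = 0.0,
    ic50_0: float = 100.0,
) -> list[tuple[float, float]]:
    """True IC50(t) for exponential activity loss to a plateau.

    Activity(t) = plateau + (100 − plateau)·exp(−ln2·t/t½); IC50 scales
    inversely with activity, so IC50(t) = IC50(0)·100/activity(t).
    """
    if half_life <= 0:
        raise ValueError("half_life must be positive")
    k = math.log(2.0) / half_life
    out = []
    for t in times:
        activity = plateau_pct + (100.0 - plateau_pct) * math.exp(-k * t)
        out.append((float(t), ic50_0 * 100.0 / activity))
    return out


def simulate_activity_tables(
    ic50_trajectory: Sequence[tuple[float, float]],
    concentrations: Sequence[float],
    hill: float = -1.0,
    top: float = 100.0,
    bottom: float = 0.0,
    cv: float = 0.05,
    seed: Optional[int] = None,
    n_replicates: int = 1,
) -> pd.DataFrame:
    """Normalized 4PL competition responses per timepoint and dilution.

    Columns: time_min, conc_nM, response_pct, replicate.  Multiplicative
    mean-one log-normal noise with coefficient of variation `cv`.
    """
    from .kinetics import four_pl

    concs = np.asarray(concentrations, dtype=float)
    if np.any(concs <= 0):
        raise ValueError("concentrations must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for time, ic50 in ic50_trajectory:
        if ic50 <= 0:
            raise ValueError(f"IC50 must be positive, got {ic50} at t={time}")
        for rep in range(n_replicates):
            resp = four_pl(concs, top, bottom, math.log10(ic50), hill)
            resp = resp * _lognormal_factor(rng, cv, len(concs))
            for c, r in zip(concs, resp):
                rows.append({"time_min": float(time), "conc_nM": float(c),
                             "response_pct": float(r), "replicate": rep})
    return pd.DataFrame(rows)


def simulate_decay_series(
    half_life: float,
    times: Sequence[float],
    cv: float = 0.10,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    y0: float = 100.0,
    plateau: float = 0.0,
) -> np.ndarray:
    """One noisy realization of a one-phase decay sampled at `times`.

    Multiplicative mean-one log-normal noise (CV `cv`) on the noise-free
    curve; the workhorse behind parameter-recovery simulations.
    """
    if half_life <= 0:
        raise ValueError("half_life must be positive")
    t = np.asarray(times, dtype=float)
    if rng is None:
        rng = np.random.default_rng(seed)
    k = math.log(2.0) / half_life
    truth = (y0 - plateau) * np.exp(-k * t) + plateau
    return truth * _lognormal_factor(rng, cv, len(t))


# --- plain-text scenario config -------------------------------------------

def _scenario_dict(scenario: SimulationScenario) -> dict:
    d = asdict(scenario)
    d["bound_pools"] = [asdict(p) for p in scenario.bound_pools]
    return d


def scenario_to_config(scenario: SimulationScenario) -> str:
    """Serialize a scenario to a plain-text ``key = value`` config."""
    lines = []
    for key, value in _scenario_dict(scenario).items():
        if key == "bound_pools":
            for p in value:
                hl = "stable" if p["degradation_half_life"] is None else p["degradation_half_life"]
                lines.append(
                    f"pool.{p['name']} = {p['kind']}:{p['fraction']}:{hl}:{p['initial_fraction']}"
                )
        elif key == "sampling_times":
            lines.append(f"sampling_times = {','.join(str(v) for v in value)}")
        else:
            lines.append(f"{key} = {value}")
    return "\n".join(lines) + "\n"


def scenario_from_config(text: str) -> SimulationScenario:
    """Parse the ``key = value`` scenario config written by
    :func:`scenario_to_config`; unknown keys raise a validation error
    listing the offenders."""
    kwargs: dict = {}
    pools: list[BoundPool] = []
    valid = set(SimulationScenario.__dataclass_fields__) - {"bound_pools"}
    bad: list[str] = []
    for raw in text.splitlines():
        line = raw.strip()
        # full-line comments only: '#' may appear inside values (e.g. JM#21)
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            bad.append(line)
            continue
        key, value = (s.strip() for s in line.split("=", 1))
        if key.startswith("pool."):
            name = key[len("pool."):]
            parts = value.split(":")
            if len(parts) not in (3, 4):
                bad.append(key)
                continue
            kind, fraction, hl = parts[0], float(parts[1]), parts[2]
            init = float(parts[3]) if len(parts) == 4 else 0.0
            pools.append(BoundPool(
                name, kind, fraction,
                None if hl == "stable" else float(hl), init,
            ))
        elif key in valid:
            fld = SimulationScenario.__dataclass_fields__[key]
            if key == "sampling_times":
                kwargs[key] = tuple(float(v) for v in value.split(","))
            elif fld.type in ("int", int):
                kwargs[key] = int(value)
            elif fld.type in ("float", float):
                kwargs[key] = float(value)
            else:
                kwargs[key] = value
        else:
            bad.append(key)
    if bad:
        raise ValueError(f"invalid scenario key(s): {sorted(set(bad))}")
    if pools:
        kwargs["bound_pools"] = tuple(pools)
    return SimulationScenario(**kwargs)
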