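# plasmalink

Thiol-bearing peptide drugs can vanish from LC-MS assays of plasma while
remaining biologically active: their free cysteine forms a disulfide
bridge with Cys34 of human serum albumin (the largest reduced-thiol pool
in plasma) and with low-molecular-weight plasma thiols, hiding the intact
peptide from direct detection. `plasmalink` implements the computational
chain needed to establish and quantify that covalent binding for CXCR4
antagonist peptides such as EPI-X4 WSC02 (`IVRWSKKVPCVS`) and EPI-X4
JM#21 (`ILRWSRKLPCVS`):

- **in-silico tryptic digestion** with missed cleavages and 1-based
  fragment positions (trypsin: cut after K/R, not before P);
- **exact monoisotopic mass arithmetic** for peptides, modifications,
  disulfide links (−2H = −2.01565 Da per bridge) and thiol adducts
  (Cys +119.0041, homoCys +133.0198, CysGly +176.0255, GSH +305.0682 Da);
- **conjugate enumeration and ppm-tolerance matching** of observed
  masses, with a reduction/carbamidomethylation consistency control and an
  arithmetic audit for composite masses that fail to match;
- **XIC quantification**: theoretical isotope patterns by per-element
  convolution, extracted-ion chromatograms at the most intense isotope
  (±20 ppm, z = 3/4 for conjugates), trapezoidal peak areas per timepoint;
- **kinetics**: one-phase decay Y(t) = (Y0 − Plateau)·e^(−Kt) + Plateau
  with t½ = ln 2 / K, and 4PL antibody-competition dose-response fits
  yielding IC50 and remaining activity IC50(0)/IC50(t) × 100;
- a **synthetic-data generator** (closed-form two-compartment kinetics,
  Gaussian elution, isotope clusters, ppm jitter, log-normal noise, decoy
  peaks) with a ground-truth manifest, so the whole pipeline is testable
  without instrument data.

## Worked example

```python
from plasmalink import (digest, cysteine_fragments, enumerate_conjugates,
                        match_masses, reduction_control, fit_one_phase_decay)
from plasmalink.synthetic import (SimulationScenario,
                                  simulate_species_kinetics, emit_peaklists)
from plasmalink.quantify import timecourse

# identify the albumin Cys34 crosslink from observed digest masses
chain = "DAHKSEVAHRFKDLGEENFKALVLIAFAQYLQQCPFEDHVKLVNEVTEFAK"  # HSA 1-51
carrier = cysteine_fragments(digest(chain, "trypsin", 1))
analyte = cysteine_fragments(digest("IVRWSKKVPCVS", "trypsin", 1))
candidates = enumerate_conjugates(carrier, analyte)
result = match_masses([2933.484], candidates, tolerance_ppm=5.0)
m = result.matches[0]
print(f"{m.candidate.label}: theoretical {m.candidate.mono_mass:.4f} Da, "
      f"observed {m.observed}, error {m.ppm:+.2f} ppm")
control = reduction_control(result.matches, [2489.2799], carrier)[0]
print(f"reduction/alkylation control: {control.status} "
      f"(CAM fragment {control.cam_fragment_mass:.4f} Da)")

# recover a plasma half-life from synthetic peak lists
scenario = SimulationScenario(seed=42)
abundances = simulate_species_kinetics(scenario)
runs = emit_peaklists(abundances, scenario, seed=42)
course = timecourse(runs, list(scenario.candidates().values()))
free = course[course.species == "JM#21"].sort_values("time_min")
fit = fit_one_phase_decay(free.time_min, free.area)
print(f"free-peptide half-life: {fit.half_life:.2f} min "
      f"(generator truth {scenario.net_free_half_life:.2f} min)")
```

prints

```
ALVLIAFAQYLQQCPFEDHVK--SS--VPCVS: theoretical 2933.4820 Da, observed 2933.484, error +0.70 ppm
reduction/alkylation control: pass (CAM fragment 2489.2777 Da)
free-peptide half-life: 1.74 min (generator truth 1.70 min)
```

The first two lines are the identification logic: the tryptic
Cys34-containing albumin fragment (residues 21-41, found at its mature-
chain position by the digester) disulfide-linked to the WSC02 fragment
VPCVS matches the observed 2933.484 Da within 0.7 ppm, and after
reduction + alkylation the crosslink disappears while the
carbamidomethylated fragment (2489.28 Da) appears — the control passes.
The last line closes the loop on synthetic data: peak lists generated
with a known 1.7 min free-peptide half-life are quantified by XIC areas
and refitted to 1.74 min.

A `plasmalink` console command exposes the same stages as subcommands
(`digest`, `conjugates`, `stability`, `activity`, `simulate`); see
`plasmalink --help`.

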