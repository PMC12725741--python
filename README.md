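# condenseq

Coarse-grained Brownian-dynamics simulation and analysis of
**sequence-dependent protein–DNA co-condensation** on tethered DNA.

Phase-separating DNA-binding proteins (transcription factors such as Sox2
or FoxA1, heterochromatin protein HP1, bacterial nucleoid-associated
proteins) form droplets *together with* the DNA they bind. On a DNA
molecule tethered at both ends — the geometry of TIRF coverslip and
optical-tweezer assays — such a co-condensate reels in slack DNA and pulls
on the bare DNA outside it with a piconewton-scale **capillary force**.
`condenseq` asks how the DNA *sequence* shapes this process: where
condensates sit, how many coexist, and how the binding affinity of the DNA
at the condensate interface sets the force.

## Model

DNA is a semiflexible bead-spring chain (one bead = 10 bp = 1 sigma =
3.4 nm, persistence length 15 beads), end-tethered at normalized extension
`Re' = Re/s` inside a periodic box; proteins are single beads at bulk
concentration `rho_p` (uM). Beads interact by shifted Lennard-Jones
attractions — `eps_PP` between proteins, a per-monomer `eps_MP(m)` between
DNA and proteins — plus WCA excluded volume, harmonic bonds and a
`kappa (1 - cos theta)` bending term, integrated with an underdamped
Langevin (BAOAB) thermostat at `T = 1 kBT`, `gamma = 0.1/tau`,
`dt = 0.01 tau`.

Sequence enters through the affinity track `eps_MP(m)`:

| model         | affinity landscape                                       |
| ------------- | -------------------------------------------------------- |
| `homogeneous` | 2.0 kBT everywhere (null model)                           |
| `het1`        | central half 2.25 kBT, flanking quarters 1.75 kBT         |
| `het2`        | five equal blocks, 0.1 / 2.25 / 0.1 / 2.25 / 0.1 kBT      |
| sequence      | AT content of 10-bp windows, 11 levels in 0.1–4.0 kBT     |

The analysis stack implements the full measurement pipeline: per-frame
DBSCAN condensate detection (`MinPts = 6`) with data-driven epsilon from
the smoothed k-distance knee, ellipsoidal condensate volumes
`Vc = 4/3 pi rx ry rz`, capillary forces from mean bond stretching
(`F = kb (ltp - lt) - kb (lt - l0)`), per-monomer occupancy `Pm`,
occupancy-weighted interfacial affinity `Ia`, kymographs, coarsening
kinetics, and persistence-length recovery.

## Worked example

```python
from condenseq import (scaled_config, build_block_profile, run_experiment,
                       detect_trajectory, occupancy, interfacial_affinity,
                       count_equilibrium_condensates)
from condenseq.scans import scaled_detection_params

config = scaled_config("het2", n_monomers=100, re_prime=0.6,
                       rho_p_um=84.50, eps_pp=2.0, eps_mp_scale=4/3, seed=11)
profile = build_block_profile("het2", 100)
traj = run_experiment(config, profile, seed=11)

params = scaled_detection_params(100)
det = detect_trajectory(traj, params)
half = det[len(det) // 2:]
print("equilibrium condensates:", count_equilibrium_condensates(half, params))
occ = occupancy(det, 100)
print("interfacial affinity:", interfacial_affinity(occ, profile).ia_mean)
```

This prints:

```
equilibrium condensates: 2
interfacial affinity: 1.980625549403173
```

The desk-scale two-block chain (blocks of twenty 2.25-kBT monomers scaled
to 3.0 kBT, separated by 0.13-kBT spacers) holds **two** stable
condensates — one per high-affinity block — where the homogeneous chain
under the same conditions coarsens to **one**. The interfacial affinity of
1.98 kBT sits between the spacer (0.13 kBT) and block (3.0 kBT) values:
the droplet interfaces cover the block edges plus a few adjacent spacer
monomers, and the occupancy weighting mixes the two.

A command-line interface mirrors the library:

```bash
condenseq simulate --config experiment.yaml --seed 1 --out traj.xyz
condenseq detect --traj traj.xyz --out detection/
condenseq scan --config experiment.yaml --re-grid 0.2,0.4,0.6,0.8 --out scan.tsv
```

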