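# sesc — subject-specific whole-body center-of-mass estimation

`sesc` estimates the 3-D whole-body center of mass (CoM) of a person from
segment kinematics alone, using a **statically equivalent serial chain
(SESC)** that is *identified per subject* from a short calibration session of
static postures recorded with a skeleton tracker (e.g. a depth camera) and a
balance board measuring the center of pressure (CoP). It is aimed at
biomechanics and rehabilitation researchers who want personalized CoM
tracking — a core metric of postural stability — without laboratory-grade
motion capture, force plates, or reliance on cadaver-derived anthropometric
tables that poorly represent elderly or neurologically impaired subjects.

## The model

The CoM of a rigid multi-body chain can be written as the end effector of an
open serial chain whose constant geometry encodes the subject's mass
distribution. With the torso as a floating root (orientation **A**₁, origin
**d**₀), a 9-segment humanoid (hands, feet and head merged into their
neighbours), on-axis limb CoMs and bilateral symmetry, the CoM reduces to

```
C = d0 + A1 r1 + (a2 + a4) r2 + (a3 + a5) r3 + (a6 + a8) r6 + (a7 + a9) r7
```

where **a**ᵢ is the global direction of segment *i*'s long axis, **r**₁ ∈ ℝ³
and r₂, r₃, r₆, r₇ are constants: seven parameters in total (torso,
upper-arm, forearm+hand, thigh, shank+foot pairs). During quiet static
stance the measured CoP equals the CoM ground projection, so each held
posture yields two linear equations in the parameters; stacking the x/y rows
over many postures gives an overdetermined system **y = D R** solved by
Moore–Penrose pseudo-inverse. Once **R** is identified, CoM estimation needs
only kinematics — including fast, dynamic movement.

Quality is graded by the regressor condition number (σmax/σmin), parameter
relative standard deviations, their ratio to the smallest one (k > 10 flags
a poorly identified parameter), and per-parameter Student-*t* significance.
A Winter-table comparator (`literature_sesc`) provides the classical,
non-subject-specific estimate; a virtual-subject simulator
(`sesc.synthetic`) stands in for all hardware.

## Worked example

Simulate a subject whose mass distribution deviates 15 % from the
literature table, identify their chain, and compare both estimators on
held-out postures:

```
$ sesc simulate --seed 11 --deviation 0.15 --noise vicon_like --n-holds 20 --out sess
$ sesc identify --skeleton sess/skeleton.csv --cop sess/cop.csv \
      --out params.json --report report.json
identified from 20 static windows; cond(D) = 15.88
...
cond(D) = 15.88   sigma_rho = 0.273 mm   dof = 33

$ sesc evaluate --session sess --split-seed 1 --n-identify 10 --out eval.json
 sesc_identified: rmse    0.33 mm  AP    0.21  ML    0.25  R^2  1.000
      literature: rmse    9.97 mm  AP    9.81  ML    1.77  R^2  0.973
```

Reading the numbers: the condition number of the stacked regressor (15.88)
is well below the warning threshold of 20, so the 20 postures excited all
seven parameters. On the validation postures, the identified chain tracks
the measured CoP to 0.33 mm rmse (AP/ML = anterior-posterior and
medio-lateral components), whereas the literature table — which does not
know this subject's mass distribution — is off by ~10 mm. `estimate` then
produces a CoM trajectory for any skeleton recording without a force plate:

```
$ sesc estimate --params params.json --skeleton sess/skeleton.csv --out com.csv
CoM trajectory (1786 samples) written to com.csv
```

The same workflow is scriptable from Python (`generate_subject`,
`generate_session`, `assemble_identification_system`, `identify`,
`estimate_com`, `compare_methods`).

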