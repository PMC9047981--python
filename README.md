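# smdcycle

Absolute binding free energies from steered simulations over a restrained
thermodynamic cycle — implemented and validated end-to-end on toy dimers
with exact quadrature oracles — plus the structural interface analyzers
that accompany such a study (ΔSASA ranking, π–π and hydrogen-bond
detection with occupancy, alanine-truncation mutants, the nonpolar
solvation term).

## Who this is for

Computing the binding free energy of a protein–protein dimer by brute
force means simulating the physical association of two flexible molecules,
which does not converge.  A practical alternative builds a *fictitious*
thermodynamic cycle: restrain both monomers (eleven geometric restraints —
a collective-variable spring, per-monomer shape and planar restraints, six
single-atom pins), pull them together along a fixed axis in the restrained
ensemble, and pay the restraints back with two release processes, one per
end state:

    ΔF  =  −ΔF_A + ΔF_B + ΔF_C + ΔF_V + ΔF_R

where B is the restrained pull, A and C release the restraints in the
unbound and bound states, ΔF_V = k_BT ln(V₀/V_u) is the standard-state
correction (V₀ = 1661 Å³) and ΔF_R = −k_BT ln(4r_b²/(Δr_y,b Δr_z,b)) the
rotational-restriction correction.  Every stage free energy comes from
repeated nonequilibrium pulls via the Jarzynski equality

    exp(−β ΔF) = ⟨ exp(−β W) ⟩,

estimated as a max-shifted log-mean-exp with bootstrap error bars.

This package provides that machinery as a library (`smdcycle`), a CLI
(`smdcycle pull/release/estimate/cycle/analyze/mutate/fixtures/simulate`),
and a set of numbered analysis drivers (`analysis/01…05`).  The simulation
engine is a BAOAB Langevin integrator for bead-model "toy" dimers whose
binding free energy is *exactly* computable by 1-D quadrature — so every
piece of the pipeline is tested against ground truth rather than against
another simulation.  See `docs/methods.md` for the model, conventions and
limitations.

## Worked example

Assemble a cycle from known stage values (the arithmetic of the five
components and the error quadrature):

```python
from smdcycle import CycleComponents, assemble_cycle

res = assemble_cycle(CycleComponents(
    dF_A=-77.88, dF_B=-25.02, dF_C=-61.66, dF_V=5.45, dF_R=-5.62,
    s_A=0.89, s_B=0.95, s_C=0.53, temperature=298.0))
print(f"dF = {res.dF:.2f} +- {res.sigma:.2f} kcal/mol")
```

```
dF = -8.97 +- 1.41 kcal/mol
```

Run the whole toy cycle — three steered processes, 40 trajectories each,
corrections measured from the released end states, closed against the
exact oracle (`python analysis/03_assemble_cycle.py`, ~3 min on one core):

```
toy thermodynamic cycle (kcal/mol):
  dF_A =  -15.962 +- 0.153   (unbound release)
  dF_B =   -2.848 +- 0.016   (pull; minimum at 3.40 A)
  dF_C =  -15.233 +- 0.139   (bound release)
  dF_V =    1.123            (standard state)
  dF_R =   -0.973            (rotational restriction)
  -A+B+C         =   -2.120 +- 0.207
  quadrature dF  =   -1.978 +- 0.0000
  closure gap    =    0.142
  corrected dF   =   -1.969 +- 0.207
```

The two release free energies are large (each pays back ten stiff
restraints) but cancel up to the physics: −ΔF_A + ΔF_B + ΔF_C lands on the
exact quadrature answer within the propagated error, and
`analysis/04_speed_convergence.py` shows the gap shrinking monotonically
(≈1.9 → 1.4 → 0.14 kcal/mol) as the steering slows 100× → 10× → 1×.

Structure analysis works on any PDB file:

```
smdcycle fixtures pi-pi --out stack.pdb -p distance=4.0 -p angle_deg=10
smdcycle analyze stack.pdb --out analysis_out
smdcycle mutate stack.pdb --chain A --resseq 1 --out mutant.pdb
```

```
pi-pi: pi-pi-parallel at 4.00 A, 10.0 deg
hydrogen-bond occupancy over 10 frames: 70%
```

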