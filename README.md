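# flashlysis

Water radiolysis chemistry under pulsed ultra-high dose rate (FLASH-regime)
electron irradiation.

Clinical FLASH radiotherapy delivers its dose in microsecond accelerator
pulses at dose rates millions of times above conventional therapy, and the
chemistry of the radio-induced species — hydrated electrons (e⁻aq),
hydroxyl radicals (•OH), superoxide (O₂•⁻), hydrogen peroxide (H₂O₂),
hydroperoxyl (HO₂•) — is one of the leading candidate mechanisms for the
normal-tissue sparing observed at these dose rates. `flashlysis` is a
simulation toolkit for that regime, aimed at computational radiation
chemists and radiobiology modellers. It provides:

- **a reaction-network layer**: species with elemental composition and
  charge, mass-action reactions with published rate constants, strict
  atom/charge balance auditing, and a packaged water-radiolysis table whose
  peroxide/superoxide core is

  | label | reaction | k (M⁻¹s⁻¹) |
  |---|---|---|
  | 1a | •OH + •OH → H₂O₂ | 5.50·10⁹ |
  | 1b | •OH + O₂•⁻ → O₂ + OH⁻ | 1.07·10¹⁰ |
  | 2a | H₃O⁺ + O₂•⁻ → HO₂• + H₂O | 4.78·10¹⁰ |
  | 2b | HO₂• + O₂•⁻ → HO₂⁻ + O₂ | 9.70·10⁷ |
  | 2c | H₃O⁺ + HO₂⁻ → H₂O₂ + H₂O | 5.00·10¹⁰ |
  | 2d | HO₂⁻ + H₂O → H₂O₂ + OH⁻ | 1.36·10⁶ |

- **a stiff kinetics engine**: the homogeneous-phase ODE system
  dC/dt = S·r(C) + inj(t), integrated with SciPy's LSODA over rectangular
  pulse trains (0.17–10 Gy per 1.8 µs pulse, 100 Hz repetition), with
  instantaneous pulses applied as discrete concentration kicks.
  Concentrations convert to G values (entities per 100 eV) through
  C = 1.0364·10⁻⁷ · G · D mol/L per gray, and in-pulse G values are
  normalized to the energy imparted by the *entire* pulse;
- **an electron-source geometry layer**: sampling of a joint
  energy × cos θ fluence distribution (µm⁻² Gy⁻¹ per bin) and disk-chord
  entry positions on a 2 µm spherical target, reproducing the parallel-beam
  chord-length law p(ℓ) = ℓ/2R² with mean chord 4R/3;
- **dosimetric bookkeeping**: dose-to-fluence conversion through the
  minimum-ionizing mass stopping power (~2 MeV·cm²/g), dose-to-energy for
  the micron sphere, and electron counts per pulse;
- **synthetic fixtures** standing in for beam-transport inputs (a
  forward-peaked + isotropic joint distribution, literature escape yields),
  so the whole pipeline runs without any external data.

## Worked example

Dosimetry cross-check and a 10 Gy / 1.8 µs single-pulse simulation:

```console
$ flashlysis report --dose 10
dose: 10.0 Gy, mass stopping power: 2.0 MeV cm^2/g
fluence: 312.1 um^-2 (31.21 um^-2 Gy^-1)
expected electrons through R=2.0 um sphere: 3.922e+03
energy for 10.0 Gy in the sphere: 2.092e+06 eV

$ flashlysis simulate --scenario 10Gy --seed 1 --out ten_gy.tsv
INFO flashlysis: scenario=10Gy mode=per_pulse_injection seed=1
INFO flashlysis: wrote ten_gy.tsv (250 time points)
```

The fluence line says that a 10 Gy pulse of ~MeV electrons corresponds to
about 312 electrons per µm², i.e. ~3.9·10³ primaries crossing the 2 µm
target sphere, which deposit 2.09 MeV in it. The series file holds
concentration and G value per species on a log time grid from 1 ns to
100 s:

```python
from flashlysis.simulate import read_series, time_to_fraction_of_peak
s = read_series("ten_gy.tsv")
# t=1.0e-05 s: G(OH)=1.65  G(H2O2)=0.95  G(O2-)=1.618
# OH half-fall time: 1.58e-05 s
```

At 10 µs the hydroxyl yield has already fallen to 1.65 (from its injected
2.8) while peroxide and superoxide build up — the hallmark of the
high dose-per-pulse regime, where radical–radical recombination outruns
scavenging. Rerunning across the four study scenarios shows the •OH
half-fall time dropping from 7.6·10⁻⁴ s at 0.17 Gy to 1.6·10⁻⁵ s at 10 Gy,
and the superoxide lifetime (time to 10 % of peak) from ~113 s to ~1.3 s:
higher dose-per-pulse means an earlier hydroxyl fall and less, shorter-lived
superoxide.

Other entry points: `flashlysis validate-network <table>` audits a reaction
table for atom/charge balance; `flashlysis sample-source --n 10000 --seed 1
--out src.tsv` writes per-electron source points and reports the mean chord
(≈ 2.667 µm at R = 2 µm).

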