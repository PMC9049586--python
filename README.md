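# pkclife

A deterministic mass-action kinetic model of the protein kinase C (PKC)
life cycle: de-novo synthesis, ordered constitutive phosphorylation
(maturation), second-messenger activation, PHLPP-mediated
dephosphorylation and down-regulation, and HSP70-mediated rescue — with a
pulse/intervention protocol engine, pre-built scenario experiments, and a
local one-at-a-time parameter sensitivity map.

It is aimed at systems biologists studying kinase homeostasis: how the
cellular PKC pool is built after a brief burst of protein synthesis, and
how the amplitude, duration and repetition of Ca²⁺/DAG- or PMA-like
stimulation decide whether the pool survives activation or is
down-regulated.

## The model

A single PKC moiety pool moves through twelve dynamical species connected
by thirteen mass-action reactions (R1–R12 plus degradation of the mature
form). Six partner species are chemostatted: the polyribosome level T,
PDK1, mTORC2, the activator (Ca²⁺/DAG/PMA, in nM), PHLPP (folded into the
pseudo-first-order dephosphorylation constant k₁₇) and HSP70.

```
R1   mRNA + T ⇌ C1                    (k₁, k₂)     transcript loading
R2   C1 → PKC + mRNA + T              (k₃, gated)  translation
R3   PKC → ∅                          (λ₁)         naive degradation
R4   PKC + PDK1 ⇌ C2 → PKC·Pᴬ + PDK1  (k₄,k₅,k₆)   activation-loop phosphorylation
R5   PKC·Pᴬ + mTORC2 ⇌ C·PKC·Pᴬ       (k₇, k₈)     mTORC2 binding
R6   PKC·Pᴬ → ∅                       (λ₂)         degradation
R7   2 C·PKC·Pᴬ ⇌ C3 → M + C·PKC·Pᴬ   (k₉,k₁₀,k₁₁) autophosphorylation seeding
R8   M + C·PKC·Pᴬ ⇌ C4 → 2 M          (k₁₂,k₁₃,k₁₄) mature-catalysed autophosphorylation
R9   M + ACT ⇌ A*                     (k₁₅, k₁₆)   second-messenger activation
R10  A* → PKCᴬ                        (k₁₇_eff)    PHLPP dephosphorylation
R11  PKCᴬ → ∅                         (λ₃)         degradation of the open form
R12  M + HSP70 + PKCᴬ ⇌ C5 → 2M + HSP70 (k₁₈,k₁₉,k₂₀) HSP70 rescue
RM   M → ∅                            (λ₄)         slow turnover of the mature pool
```

where M = C·PKC·Pᴬ·Pᴴ·Pᵀ (mature, cytosolic, catalytically competent) and
A* = (PKC·Pᴬ·Pᴴ·Pᵀ)ᴬ (membrane, active). The ODE system ẏ = S·v(y) is
integrated in seconds with a stiff implicit solver (LSODA, rtol 1e-8 /
atol 1e-12), restarted at every protocol discontinuity. "Total PKC" is
the moiety-weighted sum over species (complexes C3, C4, C5 count twice).

Protocols are square pulses under a half-open [t_on, t_on+duration)
convention: synthesis pulses gate k₃, activator pulses set the clamped
nM level, and interventions block k₁₇ (transiently or fractionally) or
scale HSP70.

## Worked example

```python
from pkclife import (Protocol, Pulse, build_default_network,
                     default_parameterization, simulate,
                     total_pkc_series, plateau_value, drop_after_pulse)

params = default_parameterization()
net = build_default_network()

# 10-min synthesis pulse, then three 15-min 0.005 nM activator pulses
proto = Protocol(
    t_end=495.0,
    synthesis_pulses=(Pulse(0.0, 10.0),),
    activator_pulses=(Pulse(50.0, 15.0, 0.005),
                      Pulse(220.0, 15.0, 0.005),
                      Pulse(360.0, 15.0, 0.005)),
)
traj = simulate(net, params, proto)
total = total_pkc_series(traj)

print(round(plateau_value(total, (40, 50), slope_tol=0.02), 2))
for pulse in proto.activator_pulses:
    print(round(drop_after_pulse(total, pulse, slope_tol=0.05,
                                 settle_delay=50.0), 2))
```

prints

```
73.02
10.0
7.12
5.0
```

— the pool stabilizes at ≈73 ng/ml after synthesis; each intermediate-
strength pulse down-regulates part of the pool, and the drop shrinks from
≈10 ng/ml (first pulse) to ≈5 ng/ml (third), because material rescued by
HSP70 is transiently sequestered in the rescue complex and unavailable to
later pulses.

The same experiments are available from the shell:

```
pkclife scenario list
pkclife scenario run fig5_sequential --outdir results/fig5
pkclife sensitivity run --outdir results/sensitivity
pkclife simulate --config run.yaml
```

Each run writes tidy trajectory CSVs, a `metrics.json`, and a resolved
configuration sufficient to reproduce it bit-for-bit.

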