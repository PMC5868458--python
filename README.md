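# bbbsim

Compartmental simulation of delphinidin delivery across the blood–brain
barrier (BBB), free and nanoparticle-encapsulated, with a categorical
protein-expression overlay for glioblastoma pathway networks.

Delphinidin is an anthocyanidin antioxidant with reported anti-tumor
activity whose entry into the brain is limited by the BBB and by
p-glycoprotein (p-gp) efflux at the luminal endothelial membrane.
`bbbsim` is aimed at researchers exploring nanoparticle delivery design:
it lets you simulate how encapsulation (which changes the effective
membrane permeability) alters the compound's concentration time courses,
sweep any model parameter, and visualise which pathway proteins are
differentially expressed in glioma versus healthy cortex.

## The models

**Transport.** The brain capillary bed is idealised as a single tube of
luminal radius r_L, endothelial outer radius r_E and aggregate length
l ≈ 600 km.  Concentrations in the capillary lumen (C_L) and endothelial
cytoplasm (C_E) obey

    dC_L/dt = (1/V_L) [ A_LE·D_LE·(C_E − C_L) + J_max·C_E/(K_M + C_E)·l ]
    dC_E/dt = (1/V_E) [ A_LE·D_LE·(C_L − C_E) + A_EM·D_EM·(C_M − C_E)
                        − J_max·C_E/(K_M + C_E)·l ]

where V_L, V_E, A_LE, A_EM follow the cylinder closed forms, D_LE is the
luminal membrane permeability (0.5 µm/min free, 34.8 µm/min encapsulated),
D_EM the abluminal permeability, the brain bath C_M is held constant, and
the Michaelis–Menten term is the saturable p-gp efflux pump (capacity
J_max per unit capillary length, half-saturation K_M).

**Release.**  Uptaken compound (pool Cu\*) feeds the released brain pool
(C\*) at the p-gp uptake rate k₂, and the released pool clears at the
release rate k₁:

    dCu*/dt = −k₂·Cu*        dC*/dt = k₂·Cu* − k₁·C*

C\*(t) is the Bateman function, peaking at t = ln(k₂/k₁)/(k₂ − k₁) —
**50.1 min** at the default rates k₁ = 0.01/min, k₂ = 0.035/min.

**Pathway overlay.**  A tab-separated expression table (shipped: 73
proteins scored in four healthy-cortex contexts and across ~12 glioma
samples) is parsed into categorical records; each protein's modal tumor
category and per-cell-type up/down flags are computed on the ordinal
scale Not Detected < Low < Medium < High, and painted onto any
user-supplied GraphML/SIF pathway graph.

## Worked example

```
$ bbbsim release
analytic peak time: 50.1105 min (value 0.605861 µM)
numerical peak: 0.605861 µM at 50.1117 min
```

The brain concentration of encapsulated delphinidin peaks ~50 min after
injection at ~61 % of the injected (uptaken) amount — the closed form and
the integrated trajectory agree to five figures.

```
$ bbbsim simulate --mode free --n-points 200
C_L_uM: peak 199.729 µM at 20 min, terminal 199.729 µM, AUC 2023.38 µM·min
C_E_uM: peak 0.0510576 µM at 20 min, terminal 0.0510576 µM, AUC 0.540246 µM·min

$ bbbsim simulate --mode encapsulated --n-points 200
C_L_uM: peak 37.7951 µM at 20 min, terminal 37.7951 µM, AUC 621.163 µM·min
C_E_uM: peak 0.99583 µM at 20 min, terminal 0.99583 µM, AUC 15.4748 µM·min
```

Starting from a 1 µM lumen bolus, the pump holds the endothelium far
below the 1 µM brain bath in free mode (0.05 µM at 20 min) while the
lumen accumulates pumped-back compound; encapsulation's 70-fold higher
luminal permeability keeps the endothelium essentially equilibrated with
the bath (0.996 µM) and the overall concentration excursion ~5× tighter.
Add `--out traj.csv --metrics m.json --plot fig.png` for files, or
override any parameter with `--set K_M=3.0` / a YAML config
(`bbbsim describe-params` lists the schema with units and provenance).

```
$ bbbsim sweep --param D_LE_1 --log-range 0.1,100,8 --out sweep.csv
$ bbbsim annotate --table src/bbbsim/data/cortex_tumor_expression.tsv \
      --graph src/bbbsim/data/synthetic_pathway.graphml --mode tumor \
      --out annotated.graphml
```

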