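# rgpri

Conceptual-DFT toolkit for predicting the sites of radical C–H
functionalization on nitrogen heteroarenes, built around two condensed
reactivity descriptors:

- the **condensed radical Fukui function (RFF)**, computed by finite
  differences of per-atom partial charges over three electronic states,

  f⁻<sub>α</sub> = q<sub>α</sub>(N−1) − q<sub>α</sub>(N),
  f⁺<sub>α</sub> = q<sub>α</sub>(N) − q<sub>α</sub>(N+1),
  f⁰<sub>α</sub> = ½(f⁻<sub>α</sub> + f⁺<sub>α</sub>);

- the **radical general-purpose reactivity indicator (R-GPRI)**

  Ξ<sub>α</sub> = (κ+1)·q⁰<sub>α</sub> − ΔN·(κ−1)·f⁰<sub>α</sub>
  (nucleophile-like substrate under electrophilic radical attack; the sign
  of both terms flips for the electrophile-like case),

  which augments the RFF with the site's condensed ground-state charge.
  κ interpolates between electrostatic control (κ ≈ +1) and electron-transfer
  control (κ ≈ −1); ΔN is the signed extent of electron transfer. The site
  with the *smallest* Ξ at a given (κ, ΔN) is the predicted point of attack.
  Scanning a (κ, ΔN) grid produces a reactivity transition table (RTT);
  majority votes over its electron-transfer ("black box"), strong
  electron-transfer ("pink box") and combined (ERRC) regions give the first-
  and second-site predictions. Which equation applies is decided by comparing
  Mulliken electronegativities χ = (I + A)/2 of the radical and the substrate.

The package also ships a rule-based evaluation harness that scores such
predictions against computed activation enthalpies (ΔH‡ at 298 K) and
experimental yield ratios, using the equivalently-reactive tie rules
(|ΔΔH‡| ≤ 2 kJ/mol, ΔEY ≤ 0.2) and the ✓ / ✓\* / ✓‡ / ! / ⨯ verdict scheme,
plus a packaged reference study of 14 nitrogen heteroarenes attacked by •CF₃
and •*i*-Pr (140 molecule–site–radical combinations).

Intended users: computational and medicinal chemists triaging candidate
C–H functionalization sites from routine single-point charge calculations
(neutral, cation, anion at the neutral geometry; Hirshfeld charges with
ring C–H hydrogens summed into their carbons work best).

## Worked example

```python
from rgpri import packaged_dataset, rff_predict, rank_reference, score_rff

study = packaged_dataset()

# Fukui-function ranking of heteroarene 1: which ring carbon reacts first?
css = study.rff_site_set("1")
print([sorted(level) for level in rff_predict(css)])
print(css.sites["C5"].f_zero)

# reference ranking and verdict for heteroarene 10 + CF3 (barrier scenario)
rd = study.reaction("10", "CF3")
print([sorted(g) for g in rank_reference(rd, "Cal").groups])
first, second = score_rff(css, study.reaction("1", "CF3"), "Exp")
print(first.symbol, second.symbol)
```

prints

```
[['C5'], ['C3'], ['C4'], ['C2'], ['C6']]
0.168
[['C2', 'C5', 'C6'], ['C3'], ['C4']]
check none
```

i.e. C5 carries the largest condensed RFF of heteroarene 1 (f⁰ = 0.168) and
is predicted first; for heteroarene 10 + •CF₃ the 2 kJ/mol rule groups C6,
C2 and C5 (barriers 22.9–24.6 kJ/mol) as equivalently reactive; and for
heteroarene 1 + •CF₃ the RFF first prediction matches the isolated-product
data (`check`) while the second rank is unscorable (`none`) because only one
product was isolated.

The same pipeline runs from the shell on user-supplied tables:

```sh
rgpri simulate --n-molecules 4 --seed 3 --dest data      # or your own charges
rgpri descriptors --charges data/charges.csv --energies data/energies.csv \
      --chi --out desc
rgpri predict --descriptors desc/descriptors_syn1.csv \
      --role electrophilic_radical --out pred
rgpri evaluate --predictions pred/predictions.json \
      --reactions data/reactions.csv --out eval
rgpri report --calls eval/calls.csv
```

An audit of the packaged study is one call away:
`rgpri.rff_scorecard()` recomputes all 112 Fukui-model verdicts and flags the
handful of cells where the published verdict table is internally inconsistent
(see `rgpri.DOCUMENTED_DEVIATIONS` and `docs/methods.md`).

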