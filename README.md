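# skeletochron

Back-calculation of sea-turtle body sizes from bone growth marks, with
mark–recapture validation and inference of the season in which growth
marks are deposited.

## The problem

Somatic growth rates of wild sea turtles are usually measured by
tagging, releasing and recapturing animals over many years.
Skeletochronology offers a faster route: humerus cross-sections of
dead-stranded turtles retain one LAG (line of arrested growth) per
year, and the diameter of each LAG records how large the bone — and
hence the animal — was when the mark was laid down. Before growth
rates derived this way can be trusted, two things must be checked for a
population: that carapace lengths back-calculated from LAG diameters
agree with lengths actually measured on the same animals, and when in
the year LAGs are deposited (which determines how calendar years are
assigned to marks).

This package reimplements that validation analysis for Hawaiian green
turtles (*Chelonia mydas*) as a tested pipeline, and ships the
published study's complete printed dataset — 10 wild turtles that were
measured, tagged and injected with the bone marker OTC
(oxytetracycline) before stranding dead — as a bundled fixture.

## The model

Back-calculation uses the body proportional hypothesis (BPH): an
individual's straightline carapace length (SCL, cm) deviates from the
population's mean bone–body allometry by a constant proportional
factor. With the mean allometry `f(D) = L_op + b (D − D_op)^c`
(diameters `D` in mm), anchoring that factor at dead recovery gives the
estimated SCL at any interior mark diameter `D`:

    L = f(D) / f(D_final) × L_final

where `D_final` is the full cross-section diameter and `L_final` the
SCL at recovery. Defaults are the published Hawaiian green-turtle fit:
`L_op = 5.1` cm, `D_op = 2.6` mm, `b = 3.127`, `c = 0.928`.

Around this equation the pipeline implements: collapsing of closely
spaced double LAGs into single annual marks; calendar-year assignment
(most recent year to the outermost LAG, with an edge-growth rule for
spring strandings); selection of the LAG nearest the tagging date, with
fallback to the OTC mark when the tagging-era LAG was destroyed by the
resorption core; an exact paired Wilcoxon signed-rank test (midranks,
dropped zeros, full enumeration of the null distribution); and
bracketing of the deposition season from OTC marks. A forward
simulator of von Bertalanffy bone growth satisfying the BPH by
construction provides ground truth for parameter-recovery tests.

## Worked example

```sh
$ skeletochron reproduce-study
```

runs the bundled fixture end to end and prints (abridged):

```
ID     Stranded     SCL str.  Tagged        SCL tag Est. SCL  Year   Diff
CM-1   1999-02-08       58.5  1997-04-23       55.1     55.1  1997    0.0
CM-4   1999-12-10       69.6  1998-12-21       69.4     69.6  1999   -0.2
...
CM-13  2003-10-19       69.5  1994-06-17       45.5     47.0  1994   -1.5
CM-14  2004-07-14       53.7  2000-05-16       51.0     51.0  2000    0.0
Mean absolute difference: 0.4 cm
Wilcoxon signed-rank: T = 8.5, N = 7, exact two-sided p = 0.391
measured: mean 58.8 +/- SD 12.3, range 44.7-83.8 cm
estimated: mean 59.0 +/- SD 12.3, range 44.3-84.6 cm

ID     OTC date      OTC SCL  LAG SCL  Year  relation
CM-1   1997-04-23       55.9     55.1  1997  lag_before_injection
CM-4   1998-12-21       69.4     69.6  1999  lag_after_injection
CM-12  1998-05-12       57.7     57.7  1998  coincident
...
Mean absolute difference +/- SE: 0.3 +/- 0.1 cm
Inferred deposition window: after 21 December, by 16 May
```

Reading this: back-calculated SCLs at tagging differ from the field
measurements by 0.4 cm on average and the exact signed-rank test finds
no systematic difference (`T = 8.5`, `N = 7` after dropping three zero
differences, `p = 0.39`), so growth rates can be taken as differences
of successive back-calculated lengths. The OTC comparison brackets LAG
deposition between late December and mid-May — spring deposition, with
CM-1 showing it can happen earlier in some individuals.

Other entry points: `skeletochron simulate | validate | timing |
report | backcalc`, and the narrative drivers under `analysis/`
(`01_reproduce_tables.py`, `02_parameter_recovery.py`,
`03_wilcoxon_calibration.py`), which write their tables under
`results/`.

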