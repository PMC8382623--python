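# stentbim

A deterministic, config-driven **budget impact model (BIM)** for peripheral
drug-eluting stents: what does a public hospital payer save, over five years,
if every patient stented for symptomatic lower-limb peripheral arterial
disease (superficial femoral artery lesions) receives the **Eluvia**
paclitaxel-eluting stent instead of the **Zilver PTX** paclitaxel-coated
stent? The package is aimed at health economists and HTA analysts who want
the projection engine as tested, reusable code rather than a spreadsheet:
every input is a typed, validated YAML config, every output is unrounded
until display, and the whole pipeline is exercised by property-based tests
on synthetic trial data.

## The model

An annual cohort of `N_t` newly stented patients is projected through two
model cycles using the 12- and 24-month arm-level outcomes of the IMPERIAL
randomised trial (clinically driven target-lesion revascularisations,
CD-TLRs; major amputations; adverse-event hospital bed-days). Year *t* of
each arm accrues

```
TLR_t   = N_t · r12 + N_{t−1} · r24          (cumulative 24-month rate, recounted)
days_t  = N_t · h12 + N_{t−1} · h24
```

with nothing beyond each cohort's second year and no mortality. Costs are
attached from two perspectives — activity-based DRG payments per event
("healthcare system") and bed-days × the national per-diem ("hospital") —
and the budget impact is the comparator-minus-intervention difference. The
bed-day intensities `h12, h24` are back-solved from the first two years of
observed day totals via `h12 = D0/N0`, `h24 = (D1 − N1·h12)/N0`, which
exactly inverts the projection. Scenario sweeps (EVP eligibility, DES use
rate, stent price, per-diem) and state/territory disaggregation exploit the
model's exact linearity in the cohort schedule. See `docs/methods.md` for
assumptions, parameter defaults and limitations.

## Worked example

```python
from stentbim import default_imperial_config, run_model, render_national_table

config = default_imperial_config()        # shipped Australian 2019 base case
result = run_model(config)
totals = result.totals()
print(f"patients treated      {totals['patients']:>12,.0f}")
print(f"CD-TLRs avoided       {totals['tlr_avoided']:>12,.1f}")
print(f"bed-days averted      {totals['days_averted']:>12,.1f}")
print(f"hospital savings      {totals['hospital_savings']:>12,.0f} AUD")
```

prints

```
patients treated            40,399
CD-TLRs avoided            4,197.7
bed-days averted          46,243.1
hospital savings        92,624,882 AUD
```

i.e. over six model years (2019–2024) the national cohort of 40,399
DES-treated patients undergoes ~4,198 fewer repeat revascularisations and
frees ~46,243 hospital bed days under all-Eluvia use, worth ≈ $92.6M AUD to
hospitals at the $2,003 per-diem. `render_national_table(result)` lays the
per-year detail out report-style (display-rounded, totals from unrounded
sums):

```
                                   Year 0 (2019)  Year 1 (2020)  Year 2 (2021)  Year 3 (2022)  Year 4 (2023)  Year 5 (2024)  Total
Zilver PTX: CD-TLRs                          509           1684           1798           1921           2052           2192  10156
Eluvia: CD-TLRs                              257            995           1063           1135           1213           1295   5959
Difference: hospital days averted           4019           7369           7872           8409           8981           9594  46243
```

Absolute healthcare-system cost *levels* depend on an unpublished index-DRG
weight and are flagged approximate; the between-arm savings structure is
exact (see `docs/methods.md`).

The same pipeline is available from the shell:

```sh
stentbim run --out-dir out            # national per-year report (CSV)
stentbim scenarios --out-dir out      # one-way sensitivity sweep
stentbim states --out-dir out         # state/territory low–high table
stentbim simulate --seed 1 --out-dir out   # synthetic config + observed days
```

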