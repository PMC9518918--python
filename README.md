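# snakeburden

Decision-analytic estimation of the economic and disease burden of
snakebite at national and regional scale.

Snakebite envenoming is a neglected tropical disease that kills tens of
thousands of people a year, overwhelmingly in rural tropical settings
where antivenom supply falls far short of need. Health ministries and
funders need burden numbers — victims, deaths, amputations, DALYs, and
societal costs — to size the problem and to argue for antivenom access,
yet most affected countries have no registry to count from.
`snakeburden` implements the standard modelling answer: a cohort decision
tree driven by country-level parameters (incidence, treatment-seeking
behaviour, antivenom supply, case fatality, unit costs), with full
probabilistic and one-way sensitivity analysis. It is aimed at health
economists and epidemiologists who want a transparent, configuration-
driven, fully reproducible implementation of that model.

## The model

**Decision tree.** Annual victims $N = I \cdot P / 10^5$ (incidence $I$
per 100,000, population $P$) seek conventional care first (probability
$p_c$) or a traditional healer, from which a fraction $p_s$ later
switches to conventional care. A victim has systemic envenoming
requiring antivenom with probability $p_e$; non-envenomed victims always
survive. Indicated victims reaching conventional care receive antivenom
with probability equal to the **access level**
$a = \min(1,\, C / (N p_e))$, where $C$ is the number of antivenom
treatment courses available per year. Treated victims may have an
adverse drug reaction (cost-bearing only) and die with probability $d$;
every untreated indicated victim — including all traditional-healer-only
victims — dies with probability $\min(1,\, \mathrm{RR}\cdot d)$, with a
default relative risk of 2.33 (95% interval 1.26–4.06). Survivors of
envenoming are amputated with probability $p_a$. The tree is evaluated
as a cohort expectation (fractional persons), never a microsimulation.

**Costs (societal perspective, 2019 USD).** Direct medical costs are
bottom-up: bed-days, antivenom courses plus logistics, ADR management,
amputation procedures, converted from local currency at a single 2019
exchange rate. Direct non-medical costs cover transport and food for
the victim and one accompanying relative. Indirect costs use the human
capital approach: episode person-days times daily income (GDP per
capita / 365), plus, for each premature death at age $a$ below the
retirement age $R = 60$,

$$ \text{loss} = \text{GDP}_{pc} \sum_{t=0}^{R-a-1}
   \left(\frac{1+g}{1+r}\right)^{t}, $$

with GDP-per-capita growth $g$ and discount rate $r = 3\%$.

**DALYs.** $\mathrm{DALY} = \mathrm{YLL} + \mathrm{YLD}$: deaths times
residual standard life expectancy at the age of death, plus cases times
disability weight times duration (residual life expectancy for the
lifelong amputation state). Undiscounted and not age-weighted, per
current WHO/GBD practice.

**Uncertainty.** Every parameter carries a point estimate and a
plausible 95% range. The PSA moment-matches a distribution to each
(beta for probabilities, gamma for costs/durations, lognormal for the
relative risk, Dirichlet for demographic shares), runs the full pipeline
for 1,000 Monte Carlo draws, and reports 95% credible intervals from the
empirical 2.5th/97.5th percentiles; region intervals are computed from
joint draws, never by summing country intervals. The one-way (tornado)
analysis sweeps each parameter across its bounds with the rest at base
case. A scenario analysis adds post-traumatic stress disorder (8% of
envenoming survivors, 2% of non-envenomed victims) as an extra YLD and
productivity-cost term.

## Worked example

Country inputs live in one YAML file per country (see
`src/snakeburden/data/country_schema.json` for the full key list). The
synthetic generator produces complete, internally consistent country
files spanning high-access/low-incidence to low-access/high-incidence
settings:

```python
from snakeburden import generate_country, run_psa
from snakeburden.pipeline import run_country
from snakeburden.reporting import make_report

cp = generate_country(7, "low_access_high_incidence", name="demo")
res = run_country(cp)          # base case: tree -> costs -> DALYs
rep = make_report(res)
psa = run_psa(cp, n=1000, seed=7)
```

For this seed the model prints:

```
population          34,605,068
incidence /100k     220.84
victims             76,422
indicated           38,099
access level        0.299
treated             5,148
deaths              4,353
amputations         1,038
YLL                 151,830
DALYs               152,697
total cost MUSD     402.2
pct indicated treated 13.5%
mortality /100k     12.58
DALYs 95% CrI       80,491 - 285,184
cost 95% CrI MUSD   216.6 - 747.0
```

Reading: of 76,422 annual victims, half are envenomed, but the antivenom
stock can cover only ~30% of them, and only 13.5% are actually treated
once traditional-healer-only care is accounted for; the resulting 4,353
deaths dominate the burden — DALYs are almost entirely YLL, and most of
the 402 M USD annual cost is discounted lifetime production lost to
premature death. The credible intervals carry the joint parameter
uncertainty through the whole pipeline.

The same pipeline is available from the shell:

```sh
snakeburden synth --seed 7 --n-countries 7 --out-dir configs/
snakeburden run configs/*.yaml --out-dir out/
snakeburden psa configs/*.yaml --seed 7 --n-draws 1000 --out-dir out/
snakeburden owsa configs/country_01*.yaml --output dalys --out-dir out/
snakeburden scenario configs/*.yaml --out-dir out_ptsd/
```

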