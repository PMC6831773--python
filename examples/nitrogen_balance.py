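"""Summarise column chemistry: removal percentages and the N mass balance.

Each flow-through column is sampled daily for influent/effluent NH4+, NO2-
and NO3- (uM N).  Removal and accretion are normalised by the amount of
substrate produced upstream; the mass balance tests whether total N out
equals total N in (a one-sample t test on the daily residual).
"""

from sipshift.chemistry import ProducedFrom, summarize_column
from sipshift.model import Treatment
from sipshift.simulate import simulate_experiment

dataset = simulate_experiment()

print(f"{'column':10s} {'treatment':10s} {'NH4 rem %':>12s} {'NO2 rem %':>12s} "
      f"{'NO3 acc %':>12s} {'balance':>8s} {'p':>7s}")
for column_id, series in dataset.chemistry.items():
    treatment = dataset.column_treatments[column_id]
    nitrite_fed = treatment is Treatment.NO2
    summary = summarize_column(
        series,
        column_id=column_id,
        no2_mode=ProducedFrom.FROM_INFLUENT if nitrite_fed else ProducedFrom.FROM_NH4,
        no3_mode=ProducedFrom.FROM_NO2 if nitrite_fed else ProducedFrom.FROM_NH4,
    )

    def fmt(stat):
        mean, sd = stat
        return "ND" if mean != mean else f"{mean:.0f} ± {sd:.0f}"

    print(
        f"{column_id:10s} {treatment.value:10s} {fmt(summary.nh4_removal_pct):>12s} "
        f"{fmt(summary.no2_removal_pct):>12s} {fmt(summary.no3_accretion_pct):>12s} "
        f"{'closed' if summary.balance_closed else 'OPEN':>8s} {summary.p_value:7.2f}"
    )

print("\nNH4-only columns remove ~99% of ammonium and accrete it as nitrate;")
print("inhibitor columns (ATU, ClO3-) remove little. A 'closed' balance means")
print("no significant N is unaccounted for (p >= 0.05).")
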