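"""Generate a synthetic oldest-old cohort panel and inspect its design.

The generator emulates a paired-birth-cohort panel survey: baseline
interview of octogenarians, follow-up waves two and four years later,
deaths with recorded dates, and covariate-dependent loss to follow-up.
"""

from cohortmslt import default_study_configs, generate_panel, write_panel

config = default_study_configs()["octogenarian_earlier"]
config.n_individuals = 2000
data = generate_panel(config, seed=1)

ind = data.individuals
print(f"cohort {data.cohort}: {data.n} individuals, waves at offsets "
      f"{tuple(int(o) for o in data.wave_offsets)} years")
print(f"baseline disabled prevalence: {(data.baseline_state == 1).mean():.1%} "
      f"(configured {config.baseline_disabled_prevalence:.1%})")
print(f"deaths observed during follow-up: {ind['dead'].sum()}")
print(f"lost to follow-up: {ind['lost'].sum()} ({ind['lost'].mean():.1%})")
print(f"women {ind['woman'].mean():.1%}, rural {ind['rural'].mean():.1%}, "
      f"some schooling {ind['schooled'].mean():.1%}")

write_panel(data, "scratch_panel.csv")
print("wrote scratch_panel.csv (long format, one row per individual-wave)")
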