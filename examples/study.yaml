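# Annotated default study configuration.
#
# Species, cases, injection depths and convection regimes to sweep.  The four
# cases combine convection (1 = yes, 2 = no) with elimination routes
# (a = anterior sink only, b = anterior + posterior sinks).
species: [rabbit, human]
cases: ["1a", "1b", "2a", "2b"]
injections: [anterior, middle, posterior]
convection_regimes: [slow, fast]   # applied to case-1 rows; middle gets both

# Discretisation.  resolution multiplies the default element size (rabbit
# 0.68 mm, human 0.95 mm -> ~30-60k cells); dt_schedule is a list of
# [t_until_days, dt_days] blocks (null t_until = until t_end).  The default
# (null) uses 0.05 d steps for the first 2 days, then 0.25 d.
resolution: 1.0
dt_schedule: null
t_end:
  rabbit: 40.0    # covers the 28.0 d slowest rabbit duration of action
  human: 90.0     # covers the 70.5 d slowest human duration of action
refine_bolus: true

# PK reduction.
threshold: 2.6    # in-vivo threshold, ug/mL (12.5 ug over 4.79 mL)
dose_mg: 1.25     # injected bevacizumab mass (0.05 mL bolus)

# Diffusion-coefficient sensitivity multipliers (human case 1a, slow, middle).
d_multipliers: [1.0, 1.5, 2.0, 3.0]

out_dir: results
seed: 0           # mesh-lattice jitter and Monte-Carlo audits only
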