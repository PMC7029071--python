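# echodens

Population density of echolocating animals from stationary acoustic
detectors, by two independent routes:

1. **Generalized random encounter model (gREM).** A fixed ultrasound
   detector with detection angle θ records a pass whenever a calling
   animal crosses its detection zone. Treating animals as randomly moving
   particles (the ideal-gas model), the count of passes z over recording
   time t converts to density through the mean profile width p̄ — the
   effective one-dimensional cross-section a moving, directionally calling
   animal presents to the sensor:

       p̄ = (r/π) · (θ·sin(α/2) − cos(α/2) + 1)        (θ > π, α < π)
       D  = z / (v · t · p̄)

   with r the acoustic detection radius, α the call-cone (signal) angle and
   v the flight speed. r is derived from source sound pressure level,
   call frequency and per-night weather through spherical spreading plus
   ISO 9613-1 atmospheric absorption. When animals fly a height Δh above
   the microphone, the sphere–plane intersection shrinks the profile to
   p̄ = 2·√(r² − Δh²)·sin(α/2).

2. **Royle–Nichols (RN) abundance model.** Nights are split into sessions
   (Scott's histogram rule on normalized night time) and call activity is
   coded to detection/nondetection per session. Latent site abundance
   N_i ~ Poisson(λ_i) links to the data through
   p_ij = 1 − (1 − r_ij)^N_i, with r_ij on a logit link of session
   covariates (temperature, humidity, session index polynomial, device)
   and λ_i on a log link of site covariates (random-forest ranked,
   correlation-pruned). Fit quality is assessed by the MacKenzie–Bailey
   parametric bootstrap (with overdispersion ratio ĉ); density is mean λ
   divided by the median home-range (MCP) area.

A synthetic-data module generates ground truth for every stage: an exact
ideal-gas movement/call simulator (the geometry oracle for the gREM), an
RN generative sampler, and an end-to-end survey faker that writes the
calls/weather/sites/sun CSV files the readers consume.

Intended users: ecologists running passive acoustic monitoring who want
absolute densities rather than activity indices, and methods developers
who need a tested, simulation-backed reference implementation of both
estimators.

## Worked example

`examples/02_grem_density.py` simulates randomly moving, directionally
calling animals around a 200° sector detector and inverts the encounter
count through the profile width:

```
mean profile width p_bar = 12.58 m (r = 30.0 m, theta = 200 deg, alpha = 42 deg)
1019 encounters over 100 simulated nights
estimated density 5.21 /km^2 (truth 5.00 /km^2)
```

The simulator knows only the movement and call geometry — recovering the
generating density validates the profile-width formula. The other
examples cover the detection-range solver (`01`), the RN fit with
bootstrap goodness of fit (`03`), and both paths end to end on a faked
survey with the comparison table (`04`):

```
        species  variant  grem_density_per_km2  rn_density_per_km2  rn_to_grem_ratio
P. pipistrellus   strict             46.338178           23.860406          0.514919
```

The RN estimate sits below the encounter-model estimate at high call
activity because coding many passes per session down to a single 0/1 loses
the activity signal.

For shell use, the same stages are exposed as a thin CLI:
`echodens detect-range | grem | rn-fit | run-all | simulate` (see
`examples/config.yaml` for the configuration format).

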