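# Group-wise generative parameters for the synthetic cohort (mean / SD).
# Units: age years, spherical_equivalent dioptres, IOP mmHg, disc_area mm^2,
# RNFL and rim widths µm, LCCI dimensionless. "healthy" eyes are the fellow
# eyes of the CRAO subjects and share subject-level age and sex with them.
groups:
  NTG:
    n: 31
    age: {mean: 62.6, sd: 17.0}
    male_fraction: 0.452
    spherical_equivalent: {mean: -0.67, sd: 2.25}
    iop_at_oct: {mean: 11.1, sd: 2.4}
    disc_area: {mean: 2.56, sd: 0.41}
    ovality: {mean: 1.05, sd: 0.07}
    hrw: {mean: 157.6, sd: 73.1}
    mrw: {mean: 111.4, sd: 42.8}
    lcci: {mean: 10.8, sd: 2.3}
    rnfl:
      global: {mean: 46.0, sd: 10.4}
      temporal_superior: {mean: 51.5, sd: 23.2}
      temporal: {mean: 40.9, sd: 12.6}
      temporal_inferior: {mean: 44.5, sd: 14.3}
      nasal_inferior: {mean: 50.8, sd: 12.9}
      nasal: {mean: 44.2, sd: 11.4}
      nasal_superior: {mean: 51.1, sd: 17.8}
    vf_mean_deviation: {mean: -21.09, sd: 7.03}
    central_corneal_thickness: {mean: 549.26, sd: 43.86}
  CRAO:
    n: 31
    age: {mean: 62.2, sd: 17.1}
    male_fraction: 0.452
    spherical_equivalent: {mean: -0.05, sd: 1.43}
    iop_at_oct: {mean: 10.9, sd: 3.1}
    disc_area: {mean: 2.55, sd: 0.46}
    ovality: {mean: 1.09, sd: 0.10}
    hrw: {mean: 326.6, sd: 130.8}
    mrw: {mean: 134.3, sd: 35.6}
    lcci: {mean: 7.1, sd: 2.1}
    rnfl:
      global: {mean: 41.7, sd: 9.8}
      temporal_superior: {mean: 48.5, sd: 14.3}
      temporal: {mean: 37.7, sd: 11.0}
      temporal_inferior: {mean: 48.4, sd: 20.0}
      nasal_inferior: {mean: 42.9, sd: 13.4}
      nasal: {mean: 37.7, sd: 9.7}
      nasal_superior: {mean: 42.9, sd: 14.7}
  healthy:
    n: 31
    age: {mean: 62.2, sd: 17.1}   # shared with the paired CRAO subject
    male_fraction: 0.452
    spherical_equivalent: {mean: -0.03, sd: 1.19}
    iop_at_oct: {mean: 10.1, sd: 1.9}
    disc_area: {mean: 2.50, sd: 0.45}
    ovality: {mean: 1.05, sd: 0.08}
    hrw: {mean: 362.2, sd: 85.8}
    mrw: {mean: 217.9, sd: 29.9}
    lcci: {mean: 7.1, sd: 1.4}
    rnfl:
      global: {mean: 101.6, sd: 10.5}
      temporal_superior: {mean: 134.2, sd: 18.2}
      temporal: {mean: 75.7, sd: 11.0}
      temporal_inferior: {mean: 149.8, sd: 19.7}
      nasal_inferior: {mean: 109.9, sd: 18.6}
      nasal: {mean: 72.2, sd: 11.3}
      nasal_superior: {mean: 116.7, sd: 26.7}
# Pre-screening pool composition: candidate counts and exclusion-reason
# frequencies used by the deterministic screening fixture.
screening_pool:
  NTG:
    n: 121
    tilted_or_torted_disc: 47
    poor_oct_quality: 29
  CRAO:
    n: 90
    incomplete_crao: 31
    neovascular_glaucoma: 5
    tilted_or_torted_disc: 11
    poor_oct_quality: 12
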