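# maldihdx

Deconvolution and kinetics analysis of MALDI-TOF hydrogen/deuterium-exchange
(HDX) mass spectra of peptic peptides.

## The problem

In an HDX experiment a protein is diluted into D2O; backbone amide hydrogens
exchange for deuterium at rates set by solvent accessibility and local
structure. After quenching and pepsin digestion, each peptic peptide is
measured by MALDI-TOF MS as a singly protonated ion. The sample is a mixture
of molecules carrying different numbers of incorporated deuteriums, so the
observed isotopic envelope is a superposition of shifted isotope patterns —
and its *shape*, not just its average mass, carries information: a bimodal
envelope reveals two conformational populations in slow equilibrium (EX1-like
behaviour) that an average mass shift would hide.

`maldihdx` resolves that superposition. For a peptide with N exchangeable
backbone amides (N = L − 1 − internal prolines) it:

1. builds theoretical isotopic envelopes A_k for every incorporation count
   k = 0..N — the natural CHNOS isotope pattern of the ion, shifted by
   k × 1.006277 Da, convolved with a binomial occupancy model for the
   fast-exchanging side-chain/terminal sites (solvent D fraction 0.9 by
   default, matching a 1:9 H:D exchange buffer);
2. quantifies each observed isotopic peak by its area in a ±0.3 Da window
   around the theoretical position;
3. solves the non-negative least-squares problem

   min‖A·f − y‖² s.t. f ≥ 0, then renormalizes f to a composition
   profile with Σf_k = 1,

   reporting the abundance fraction f_k per deuterium count, the average
   number of exchanged atoms ⟨k⟩ = Σ k·f_k, the average deuteration ratio
   100·⟨k⟩/N (%), the fit residual, and the fitted per-component spectra.

Uptake time courses D(t) are fit with the single-exponential model

    D(t) = D_inf − A·exp(−k_obs·t)

where D_inf is the asymptotic uptake (%), A the amplitude resolved within the
observation window, k_obs the apparent first-order rate constant (min⁻¹) and
D_0 = D_inf − A the zero-time uptake from sites exchanging faster than the
first sampled time. Region-specific uptake for nested peptic fragments is
derived by amide-weighted subtraction. A seeded simulator generates synthetic
spectra and time courses with known ground truth for validation.

## Worked example

Simulate an angiotensin II (DRVYIHPF, 6 exchangeable amides) spectrum in
which 93.7% of molecules carry 6 amide deuteriums and 6.3% carry 5, with 1%
additive noise, and deconvolute it back:

```bash
maldihdx simulate --sequence DRVYIHPF --name angII \
    --profile '5:0.063,6:0.937' --noise-sd 0.01 --seed 42 \
    --out spectra/angII_t15min.txt
printf 'name,sequence,start,end\nangII,DRVYIHPF,1,8\n' > fragments.csv
maldihdx deconvolve --fragments fragments.csv --spectra spectra --out-dir out
cat out/results.csv
```

```
spectrum,fragment,time_min,n_amide,f_0_pct,f_1_pct,f_2_pct,f_3_pct,f_4_pct,f_5_pct,f_6_pct,avg_exchanged,deut_ratio_pct,residual_norm
angII_t15min,angII,15.0,6,0.0,0.0,0.3476,0.0,0.0,6.0114,93.641,5.925981,98.766353,0.00785782
```

Reading the row: the NNLS profile recovers the two generating populations
(6.0% at k=5, 93.6% at k=6, versus the true 6.3%/93.7%) despite the noise;
`avg_exchanged` ≈ 5.93 of the 6 amide sites carry deuterium on average, a
deuteration ratio of ≈ 98.8%. The time point (15 min) was parsed from the
`t15min` token in the file name. At zero noise the recovery is exact:
5.937 atoms and 98.95%. Per-spectrum files `*.fitted.tsv` hold the fitted
total and per-component peak areas for overlaying on the observed envelope,
and `run.json` records the parameters and seed for bit-identical reruns.

Kinetics fitting takes a CSV of `fragment,state,time_min,D_pct[,sd_pct]` and
writes one row of `D_inf, A, k_obs, D_0` (each ± 1σ) per fragment and state:

```bash
maldihdx kinetics uptake.csv fits.csv
```

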