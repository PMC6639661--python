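# nichehybrid

Niche, neutral, or both? `nichehybrid` classifies 16S OTU communities by the
shape of their rare-to-modal sequence-distance distribution, for microbiome
researchers who want to know whether a sample's rare taxa look like
selected satellites of the abundant taxa (niche assembly), like a randomly
scattered cloud (neutral assembly), or like a mixture of the two (a hybrid
community containing a neutrally assembled subpopulation).

## The method

For one sample with aligned OTU representative sequences of common length L
and read counts:

1. Split OTUs at relative-abundance threshold k (default 5%) into **modal**
   (abundant) and **rare**.
2. For each rare OTU, compute its normalized Hamming distance
   `H_ij = (1/L) Σ_α [1 − δ(S_α^i, S_α^j)]` to every modal OTU and keep the
   minimum, E_k (a Voronoi assignment in sequence space).
3. Under neutral assembly {E_k} forms a bell just below 3(L−M)/(4L), where M
   is the number of conserved alignment columns; under niche assembly it
   concentrates near zero; a hybrid community shows both peaks.
4. Test {E_k} for multimodality with Silverman's smoothed-bootstrap test
   (critical bandwidth h_crit, p = share of bootstrap replicates needing
   more than one mode). A rejection with a density mode at the neutral
   end-member calls the sample **HYBRID**; otherwise the mode location
   decides **NICHE** vs **NEUTRAL**.
5. Compare groups of samples by their hybrid fraction with a two-sided
   Fisher's exact test.

A synthetic-community simulator generates ground-truth neutral, niche and
hybrid communities so the whole pipeline is verifiable without any external
data. See `docs/methods.md` for the full model description and numerical
choices.

## Worked example

Simulate a half-niche community (600 OTUs, alignment length 400, 100
conserved columns, 8 modal OTUs, niche radius 3) and classify it:

```bash
nichehybrid simulate --alpha 0.5 --seed 5 --out-prefix demo
nichehybrid classify --fasta demo.fasta --abundance demo_abundance.tsv \
    --n-boot 199 --seed 11 --out call.json --plot demo.png
```

which prints

```
demo: HYBRID (p=0.005, h_crit=0.2636, n_rare=592, n_modal=8)
```

The 592 rare OTUs needed a critical bandwidth of 0.26 — far more smoothing
than unimodal data of this size would require — so the bootstrap p-value
hits its floor (1/200): the distance distribution has a second peak, and the
kernel-density plot in `demo.png` shows it sitting at the neutral
end-member near 3(L−M)/(4L) = 0.5625. The community is called HYBRID: its
rare taxa include both niche satellites and a neutrally scattered
subpopulation, matching the simulated alpha = 0.5.

The same analysis is available as a library:

```python
from nichehybrid import AnalysisConfig, analyze_table, simulate_community, SyntheticCommunitySpec

table, labels = simulate_community(SyntheticCommunitySpec(alpha=0.5, seed=5))
call, distances = analyze_table(table, AnalysisConfig(n_boot=199, seed=11))
print(call.classification, call.silverman.p_value)   # HYBRID 0.005
```

Cohorts are compared with `nichehybrid compare --calls CALLS.json --groups
GROUPS.tsv --out CMP.json`, which prints per-group hybrid fractions in the
form `66.67% (20/30)` and the Fisher p-value.

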