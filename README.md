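# survsig

Discovery of small gene signatures that stratify a patient cohort into
survival-distinct groups, and consensus integration of the resulting
dichotomies into stable prognosis classes.

The pipeline:

1. **Seed screening** — every gene is tested for bimodal expression
   (one- vs two-component Gaussian mixture compared by BIC) and, if bimodal,
   for survival separation of its two-group k-medians split (log-rank test,
   multiplicity-corrected).
2. **Greedy growth** — starting from each seed, the gene that maximizes the
   increase of the log-rank distance between the survival curves of the
   k-medians dichotomy (computed on the robustly standardized expression of
   current members plus the candidate) is admitted, until no candidate
   strictly improves the distance.
3. **Pruning** — members that do not significantly contribute are removed
   iteratively: a member is dropped while its importance index
   (`1 - D(without gene)/D(with gene)`) is at or below a threshold, or while
   its expression fails to separate the signature's two groups (Welch test
   at a Bonferroni-over-all-probes level). The seed itself is removable.
4. **Ensemble integration** — each signature's dichotomy is oriented
   (good/poor) by restricted-mean survival, pairwise dichotomy disagreement
   is clustered into a dendrogram, samples are classified stable-good /
   stable-poor / uncertain by an 80% consensus rule, and genes are ranked by
   occurrence count and mean importance across signatures. A downstream
   differential-expression + two-cluster + silhouette analysis of the stable
   groups is included.

A synthetic-cohort generator (`survsig.simulate`) produces cohorts with
planted bimodal signature genes tied to a latent risk class, a
class-dependent hazard, right censoring, bimodal decoys and unimodal
background — with recorded ground truth, so the whole pipeline is testable
offline.

## CLI

```sh
# generate a synthetic cohort with ground truth
survsig simulate --n-samples 200 --n-background 990 --n-signature-genes 10 \
    --hazard-ratio 3.0 --censor-rate 0.3 --seed 1 --out-dir cohort/

# seed screening only
survsig seeds --expr cohort/expression.tsv --clinical cohort/clinical.tsv \
    --alpha 0.05 --correction bh --out seeds.tsv

# full pipeline: signatures, stability classes, ranking, dendrogram
survsig run --expr cohort/expression.tsv --clinical cohort/clinical.tsv \
    --out-dir results/

# re-integrate saved signatures; adds DEG table and silhouette
survsig ensemble --signatures results/signatures.tsv \
    --expr cohort/expression.tsv --clinical cohort/clinical.tsv --out-dir ens/

# Kaplan-Meier plot of the stable prognosis groups
survsig report --clinical cohort/clinical.tsv --stability results/stability.tsv \
    --out km.png
```

Expression input is TSV/CSV (probes x samples, header = sample ids) or a GEO
series-matrix text file (`--dialect geo-series-matrix`). The clinical table
needs columns `sample_id`, `time`, `event` (event 1 = death observed,
0 = censored). Samples are aligned between the two inputs and ordered
lexicographically by id; that order is canonical for all outputs.

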