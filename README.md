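# rknet

Unsupervised refinement of radiological image stacks. Raw DICOM series or
NIfTI volumes are converted into windowed per-slice images, each slice is
embedded with a pluggable feature extractor, the embeddings are clustered
with a from-scratch K-means (k = 2), and the two clusters are mapped to
*relevant* (tumor-level) vs *irrelevant* slices. Outputs are sorted PNG
folders plus a CSV classification manifest. A synthetic phantom generator
with per-slice ground truth makes the whole pipeline testable offline.

## Layout

| module                   | role                                                                  |
|--------------------------|-----------------------------------------------------------------------|
| `rknet.imgio`            | DICOM/NIfTI ingestion, anonymization, axial splitting, CT windowing, PNG I/O |
| `rknet.features`         | 64-d reference extractor, CNN-adapter contract, z-scoring             |
| `rknet.clustering`       | Lloyd K-means with k-means++ restarts and single-point refinement, exhaustive oracle, cluster→relevance rules |
| `rknet.pipeline`         | orchestration, folder sorting, CSV/JSON manifests                     |
| `rknet.metrics`          | TPR / specificity / FPR / FNR / accuracy from confusion counts        |
| `rknet.synthetic`        | phantom cohorts (NIfTI or DICOM) with truth tables and patient splits |
| `rknet.diagnostic_demo`  | linear-softmax SGD classifier comparing filtered vs unfiltered training arms |

No DICOM library ships in the target environment, so `rknet._dicomlite`
implements the minimal codec the package needs (Part-10, explicit VR little
endian, single uncompressed 16-bit frame, no sequences).

## CLI

```sh
# write a synthetic cohort (NIfTI + truth CSVs)
rknet simulate --spec spec.yaml --output cohort/ --seed 1

# convert any DICOM/NIfTI inputs to windowed PNGs
rknet ingest --input cohort/ --output png/ --window-center 40 --window-width 400

# full filtering run: sorted folders + manifest.csv + run_manifest.json
rknet filter --input cohort/ --output filtered/ --rule foreground-mass --seed 1

# five-index report from two key,label CSVs
rknet evaluate --pred pred.csv --truth truth.csv --positive-label Class1

# train the toy diagnostic classifier per filtering arm
rknet demo --separation 3.0 --steps 400 --seed 0 --out demo/
```

`rknet filter` accepts `--scope per-series|pooled`, `--rule
foreground-mass|exemplar|majority-size`, `--exemplars FILE` (CSV of
known-relevant `patient_id,series_id,slice_index` keys) and `--config FILE`
(YAML with `windowing`, `extractor`, `clustering`, `mapping` sections plus a
top-level `seed`).

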