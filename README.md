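# tandemhor

Per-read detection and classification of higher-order repeat (HOR) structure
in satellite-DNA-containing long reads — no assembly required.

Given quality-assessed long reads and a monomer training set (e.g. ~171 bp
alpha-satellite consensus monomers), `tandemhor`:

1. **detects monomers** on both strands of each read (built-in k-mer-seeded
   aligner, or ingestion of an external profile-HMM hit table such as
   `nhmmer --tblout` output);
2. **clusters** each read's monomers by pairwise edit-distance identity
   (`1 − D/max(|a|,|b|)`, band-doubling O(ND) aligner), scanning thresholds
   from 98% down to 88% in 1% steps and keeping the highest threshold at
   which every cluster has ≥ 2 members;
3. **classifies** the read against four regularity conditions — multi-member
   clusters, within-cluster spacing within [0.95, 1.05] of the pooled median
   distance, head-to-tail gaps ≤ 5 bp, consistent orientation per cluster —
   as `regular` (with an HOR period estimate and per-cluster + full-unit
   consensus sequences), `irregular` (inversions flagged), or `no-HOR`
   (monomeric satellite flagged when all inter-monomer identities fall below
   88%);
4. **reports transitions**: uncovered intervals ≥ 1 kb are flagged and
   exported as FASTA + BED for external repeat-library annotation.

Coordinates are 0-based half-open on the forward strand throughout.

## CLI

```sh
# full pipeline: summary.tsv, consensus.fasta, monomers.tsv,
# transitions.bed/.fasta, manifest.json
tandemhor scan reads.fasta -m monomers.fasta -o outdir

# from a precomputed nhmmer --tblout hit table instead
tandemhor classify reads.fasta --hits hits.tbl --hits-format tblout -o outdir

# detection only
tandemhor detect reads.fasta -m monomers.fasta -o hits.tsv

# synthetic fixtures with ground truth (reads, truth TSV, monomer BED,
# training FASTA); deterministic per seed
tandemhor simulate -o sim -n 20 --seed 7 -k 12 -u 2 --anomaly inversion:1:3

# aggregate category counts from a summary TSV
tandemhor report outdir/summary.tsv
```

All thresholds (minimum monomer length 150, identity scan 0.98–0.88,
spacing band 0.95–1.05, maximum gap 5, transition cutoff 1000, read length
filter 2000) are exposed as flags or via `--config config.json`; flags
override the file.

The per-read summary TSV columns are: `read_id`, `read_length`,
`n_monomers`, `n_clusters`, `selected_threshold`, `classification`,
`inversion_flag`, `monomeric_flag`, `hor_period` (prefixed `~` when
approximate, for irregular reads), `median_monomer_identity`,
`n_nonsat_bases`, `nonsat_intervals`; missing values are `.`.

## Library use

```python
from tandemhor import (
    read_fasta, detect_monomers, select_threshold, evaluate_regularity,
    classify_read, process_read, PipelineConfig,
)
from tandemhor.detect import MonomerModel

reads = read_fasta("reads.fasta")
models = [MonomerModel("cons", "ACGT...")]
result = process_read(reads[0], models=models, config=PipelineConfig())
print(result.classification.label, result.classification.hor_period)
```
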