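#!/usr/bin/env bash
# Full pipeline from the shell: simulate -> embed -> pseudotime ->
# lineages -> quality.  Writes everything into ./cli_demo.
set -euo pipefail
mkdir -p cli_demo && cd cli_demo

poincaremaps simulate --kind tree --n-branches 5 --points-per-branch 30 \
    --noise-sd 0.5 --seed 1 --out-prefix tree

poincaremaps embed tree_matrix.csv --k 15 --sigma 2.0 --gamma 2.0 \
    --seed 1 --root-id cell_0 --n-lineages 5

poincaremaps quality tree_matrix.csv embedding.csv --k-geodesic 20

echo "--- quality.csv ---"
cat quality.csv
echo "--- manifest.json (excerpt) ---"
python -c "import json; m=json.load(open('manifest.json')); \
print({k: m[k] for k in ('k','sigma','gamma','epochs_run','final_loss')})"
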