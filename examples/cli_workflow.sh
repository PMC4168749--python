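#!/usr/bin/env bash
# Full command-line workflow: generate a fixture, import it as a user-defined
# organism, add a network and an expression profile, then query and
# cross-validate.  Outputs land in ./scratch/cli-demo.
set -euo pipefail

OUT=scratch/cli-demo
rm -rf "$OUT" && mkdir -p "$OUT"

funcnet make-fixture --out "$OUT/fixture" --seed 5
funcnet import-organism "$OUT/fixture/genome.tsv" --db "$OUT/db" --organism-name demo
funcnet import-network "$OUT/fixture/edgelists/physical-interaction-1.tsv" \
    --db "$OUT/db" --name ppi --group physical-interaction
funcnet import-profile "$OUT/fixture/profile.tsv" --db "$OUT/db" --top-k 20
funcnet import-attributes "$OUT/fixture/attributes.tsv" --db "$OUT/db"

printf 'G0000\nG0001\nG0002\nG0003\nG0004\n' > "$OUT/query.txt"
funcnet query --genes "$OUT/query.txt" --db "$OUT/db" \
    --weighting adaptive --related 10 \
    --annotations "$OUT/fixture/annotations.tsv" --out "$OUT/result"

funcnet crossval --db "$OUT/db" --term-file "$OUT/fixture/annotations.tsv" \
    --folds 5 --seed 5 --out "$OUT/cv.json"

echo "--- ranked genes (nodes.tsv) ---"
head -8 "$OUT/result/nodes.tsv"
echo "--- display edges ---"
head -4 "$OUT/result/edges.tsv"
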