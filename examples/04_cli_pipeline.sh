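#!/bin/sh
# End-to-end shell pipeline on a simulated study.
# Emits PDB files + metadata, derives the three thermal potentials,
# predicts every protein's stability curve in leave-one-family-out
# cross-validation, and summarises the Tm predictions.
set -e

OUT=${1:-/tmp/thermocurve_demo}

thermocurve simulate --out "$OUT/study" --n-structures 12 --seed 0

cat > "$OUT/config.yaml" <<EOF
identity_cap_pct: 100.0   # random toy sequences; real studies keep 25
tm_cutoff_c: 60.0
EOF

thermocurve build-potentials --metadata "$OUT/study/metadata.tsv" \
    --out "$OUT/potentials" --config "$OUT/config.yaml"
thermocurve predict --metadata "$OUT/study/metadata.tsv" \
    --potentials "$OUT/potentials" --out "$OUT/predictions.csv" \
    --config "$OUT/config.yaml"
thermocurve evaluate --predictions "$OUT/predictions.csv" \
    --metadata "$OUT/study/metadata.tsv" --out "$OUT/summary.tsv" \
    --config "$OUT/config.yaml"
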