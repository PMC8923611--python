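#!/bin/sh
# Shell pipeline: synthesize a problem, register it, inspect the metrics.
# Outputs are NIfTI volumes plus a machine-readable convergence log.
set -e

OUT=${TMPDIR:-/tmp}/diffeoreg-demo
rm -rf "$OUT"

diffeoreg synth --seed 42 --dims 64 --magnitude 0.3 -x "$OUT/problem"

diffeoreg register \
    -mr "$OUT/problem/reference.nii.gz" \
    -mt "$OUT/problem/template.nii.gz" \
    -x "$OUT/result"

diffeoreg metrics --result "$OUT/result"
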