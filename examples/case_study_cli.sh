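#!/bin/sh
# End-to-end shell pipeline: simulate a cohort, fit the cure model, classify,
# and produce the exCox1 / exCox2-LRM / exCox3-RITI comparison report for a
# case-study-style analysis of a user-supplied subject table.
#
# The subject table is plain delimited text with columns
#   id  x1..xg  t_e  delta_e  t_o  delta_o
# (times in months; 1 = event observed, 0 = censored).  Here the table is
# generated by the simulator; replace cohort.tsv with real data to analyse it.
set -e
OUT=${TMPDIR:-/tmp}/ritisurv-case-study
mkdir -p "$OUT"

ritisurv simulate --config "$(dirname "$0")/case_study_config.yaml" --out "$OUT/cohort.tsv"
ritisurv fit-cure --data "$OUT/cohort.tsv" --out "$OUT/cure_fit.txt"
ritisurv classify --data "$OUT/cohort.tsv" --method riti --seed 1 --out "$OUT/labels.tsv"
ritisurv estimate --data "$OUT/cohort.tsv" --labels "$OUT/labels.tsv" --estimator excox
ritisurv case-study --data "$OUT/cohort.tsv" --seed 1
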