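# Packaged model files

- `example.bnet` - the seven-node illustration network (logic rules; the
  transcription of rules B, D, F is documented in the file header).

## Transcribing the full biological models

`pckernel.mapk_fixture()` and `pckernel.cancer_fixture()` look for two
files that are **not** shipped, because the published source models are
distributed as supplementary spreadsheets that must be transcribed by hand:

- `mapk.bnet` - the 53-node / 88-link MAPK logic model, one
  `Node, expression` line per rule (`&`, `|`, `!` operators).
- `cancer.csv` - the 96-node / 265-link cancer signaling threshold model
  as `source,target,weight` rows with signed integer weights.

Place the transcriptions here and the loaders (and the tests that depend
on them) pick them up.  A transcription should carry a `#` header noting
its source and date, and for `cancer.csv` the tie policy (`zero` or
`retain`) that reproduces the source model's attractors.
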