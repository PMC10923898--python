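# AlphaFold DB models for the sticker worked examples

The two worked-example targets (SERPINB4 and PGM1 charged-sticker counts)
need the AlphaFold DB **v4** human models placed in this directory:

```
curl -O https://alphafold.ebi.ac.uk/files/AF-P48594-F1-model_v4.pdb   # SERPINB4
curl -O https://alphafold.ebi.ac.uk/files/AF-P36871-F1-model_v4.pdb   # PGM1
```

The build environment for this repository has no route to
`alphafold.ebi.ac.uk`, so the files could not be bundled.  When they are
present, `tests/test_acceptance.py::test_sticker_worked_example` and
`scripts/acceptance.py` pick them up automatically; when absent, the
tests fail with an explanatory message and the acceptance script omits
targets t1/t2.
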