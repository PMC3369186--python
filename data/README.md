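# Reference data

`NC_001137_2.fasta` — *Saccharomyces cerevisiae* chromosome V (RefSeq
accession **NC_001137.2**, ~0.6 Mb) — is required by the yeast node-count
experiment (`tests/test_acceptance.py::test_yeast_chromosome_v_experiment`
and targets t1–t6 of `scripts/acceptance.py`).

The file is **not** bundled: the build environment had no network route to
NCBI (only an internal package mirror), so it could not be vendored.  To
enable those targets, download the sequence and place it here, e.g.:

```sh
curl -s 'https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi?db=nuccore&id=NC_001137.2&rettype=fasta&retmode=text' \
    -o data/NC_001137_2.fasta
```

Everything else in the package (all other tests, the simulator, the CLI)
is fully self-contained.
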