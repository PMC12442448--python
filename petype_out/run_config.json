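{
  "command": "classify",
  "fasta": "/tmp/pytest-of-root/pytest-10/test_classify_empty_fasta_erro0/empty.fasta",
  "reference_fasta": "/tmp/pytest-of-root/pytest-10/test_classify_empty_fasta_erro0/reference.fasta",
  "annotation": "/tmp/pytest-of-root/pytest-10/test_classify_empty_fasta_erro0/annotation.tsv",
  "pdb": null,
  "templates": null
}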