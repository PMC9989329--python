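{
  "_comment": "Distilled structural rules for ENA SRA XML documents. Synthetic stand-in for offline use: hand-written from the public SRA schema structure (required elements/attributes, controlled vocabularies, reference attributes); not a copy of the XSD files.",
  "study": {
    "root": "STUDY_SET",
    "record": "STUDY",
    "required_attrs": ["alias"],
    "required_paths": [
      "DESCRIPTOR",
      "DESCRIPTOR/STUDY_TITLE",
      "DESCRIPTOR/STUDY_TYPE"
    ],
    "enums": [
      {
        "path": "DESCRIPTOR/STUDY_TYPE",
        "attr": "existing_study_type",
        "values": [
          "Whole Genome Sequencing",
          "Metagenomics",
          "Transcriptome Analysis",
          "Epigenetics",
          "Synthetic Genomics",
          "Cancer Genomics",
          "Population Genomics",
          "Exome Sequencing",
          "Pooled Clone Sequencing",
          "Transcriptome Sequencing",
          "Other"
        ]
      }
    ]
  },
  "sample": {
    "root": "SAMPLE_SET",
    "record": "SAMPLE",
    "required_attrs": ["alias"],
    "required_paths": [
      "SAMPLE_NAME",
      "SAMPLE_NAME/TAXON_ID"
    ],
    "enums": [
      {
        "path": "SAMPLE_NAME/TAXON_ID",
        "pattern": "[0-9]+"
      }
    ]
  },
  "experiment": {
    "root": "EXPERIMENT_SET",
    "record": "EXPERIMENT",
    "required_attrs": ["alias"],
    "required_paths": [
      "STUDY_REF",
      "DESIGN",
      "DESIGN/SAMPLE_DESCRIPTOR",
      "DESIGN/LIBRARY_DESCRIPTOR",
      "DESIGN/LIBRARY_DESCRIPTOR/LIBRARY_STRATEGY",
      "DESIGN/LIBRARY_DESCRIPTOR/LIBRARY_SOURCE",
      "DESIGN/LIBRARY_DESCRIPTOR/LIBRARY_SELECTION",
      "DESIGN/LIBRARY_DESCRIPTOR/LIBRARY_LAYOUT",
      "PLATFORM"
    ],
    "enums": [
      {
        "path": "DESIGN/LIBRARY_DESCRIPTOR/LIBRARY_STRATEGY",
        "values": ["WGS", "WGA", "WXS", "RNA-Seq", "miRNA-Seq", "ncRNA-Seq", "AMPLICON", "ChIP-Seq", "Bisulfite-Seq", "CLONE", "POOLCLONE", "FL-cDNA", "EST", "Hi-C", "ATAC-seq", "Targeted-Capture", "OTHER"]
      },
      {
        "path": "DESIGN/LIBRARY_DESCRIPTOR/LIBRARY_SOURCE",
        "values": ["GENOMIC", "TRANSCRIPTOMIC", "METAGENOMIC", "METATRANSCRIPTOMIC", "SYNTHETIC", "VIRAL RNA", "GENOMIC SINGLE CELL", "TRANSCRIPTOMIC SINGLE CELL", "OTHER"]
      },
      {
        "path": "DESIGN/LIBRARY_DESCRIPTOR/LIBRARY_SELECTION",
        "values": ["RANDOM", "PCR", "RANDOM PCR", "RT-PCR", "cDNA", "size fractionation", "MDA", "Restriction Digest", "Inverse rRNA", "unspecified", "other"]
      },
      {
        "path": "DESIGN/LIBRARY_DESCRIPTOR/LIBRARY_LAYOUT",
        "child_tag": true,
        "values": ["SINGLE", "PAIRED"]
      },
      {
        "path": "PLATFORM",
        "child_tag": true,
        "values": ["ILLUMINA", "OXFORD_NANOPORE", "PACBIO_SMRT", "ION_TORRENT", "BGISEQ", "DNBSEQ", "LS454", "ABI_SOLID", "CAPILLARY", "ELEMENT", "HELICOS", "COMPLETE_GENOMICS", "ULTIMA"]
      }
    ]
  },
  "run": {
    "root": "RUN_SET",
    "record": "RUN",
    "required_attrs": ["alias"],
    "required_paths": [
      "EXPERIMENT_REF",
      "DATA_BLOCK",
      "DATA_BLOCK/FILES",
      "DATA_BLOCK/FILES/FILE"
    ],
    "enums": [
      {
        "path": "DATA_BLOCK/FILES/FILE",
        "attr": "filetype",
        "values": ["fastq", "bam", "cram", "fasta", "tab", "other"]
      },
      {
        "path": "DATA_BLOCK/FILES/FILE",
        "attr": "checksum_method",
        "values": ["MD5"]
      },
      {
        "path": "DATA_BLOCK/FILES/FILE",
        "attr": "checksum",
        "pattern": "[0-9a-f]{32}"
      }
    ]
  },
  "submission": {
    "root": "SUBMISSION",
    "record": "SUBMISSION",
    "required_attrs": ["alias"],
    "required_paths": [
      "ACTIONS",
      "ACTIONS/ACTION"
    ],
    "enums": []
  }
}
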