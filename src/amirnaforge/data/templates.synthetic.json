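{
  "_comment": "Precursor insert templates for B/c oligo cloning. Loop sequences are SYNTHETIC stand-ins with the documented lengths (OsMIR390 distal loop = 16 nt; the AtMIR390a loop stand-in is longer, preserving the relative oligo-length ordering). Layout: top strand core = amiRNA + loop + amiRNA*; forward oligo = forward_overhang + core[1..L-2]; reverse oligo = reverse_overhang + revcomp(core[3..L]).",
  "forward_overhang": "CTTG",
  "reverse_overhang": "CATG",
  "templates": {
    "OsMIR390": {
      "loop": "ATTCGTTATCTTGCAG",
      "loop_origin": "synthetic 16-nt stand-in (Os distal stem-loop length)",
      "oligo_length": 60
    },
    "OsMIR390-AtL": {
      "loop": "ATTCGTTATCTGATTCACGGTAGCTTGCAGG",
      "loop_origin": "synthetic 31-nt stand-in (At distal stem-loop)",
      "oligo_length": 75
    },
    "AtMIR390a-OsL": {
      "loop": "ATTCGTTATCTTGCAG",
      "loop_origin": "synthetic 16-nt stand-in (Os distal stem-loop length)",
      "oligo_length": 60
    },
    "AtMIR390a": {
      "loop": "ATTCGTTATCTGATTCACGGTAGCTTGCAGG",
      "loop_origin": "synthetic 31-nt stand-in (At distal stem-loop)",
      "oligo_length": 75
    }
  }
}
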