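{
  "_comment": "SYNTHETIC classification fixture. Topology and nomenclature follow the standard mtDNA tree (L3 root; M and N sisters; R under N; the N(xR) clades of the route analysis). Key positions are the real ones where the field's literature names them (N defined by reversions at 8701/9540/10398/10873/15301; R by 12705!+16223!; N1'5 shares 1719; A's motif; M42b's 95C transversion; N9's 5417). All other motif positions are synthetic placeholders chosen to reproduce the published per-clade counts of defining mutations; do not use this file to classify real data.",
  "haplogroups": [
    {"name": "L3", "parent": null,
     "motif": ["769", "1018", "16311", "8701", "9540", "10398", "10873", "15301", "12705", "16223"]},
    {"name": "M", "parent": "L3", "motif": ["489", "10400", "14783"]},
    {"name": "M42b", "parent": "M", "motif": ["95C", "1888", "8952", "16304"]},
    {"name": "N", "parent": "L3", "motif": ["8701!", "9540!", "10398!", "10873!", "15301!"]},
    {"name": "R", "parent": "N", "motif": ["12705!", "16223!"]},
    {"name": "R0a", "parent": "R", "motif": ["64", "2442", "3847", "16126"]},
    {"name": "N1'5", "parent": "N", "motif": ["1719"]},
    {"name": "N1", "parent": "N1'5", "motif": ["10238", "12501", "16265"]},
    {"name": "N1a3a", "parent": "N1", "motif": ["2639", "5471", "9300", "16129"]},
    {"name": "N5", "parent": "N1'5", "motif": ["1700", "3921", "5063", "8110", "11016", "12639", "16111"]},
    {"name": "N2", "parent": "N", "motif": ["1598", "4960", "9941", "13965", "16201"]},
    {"name": "N3", "parent": "N", "motif": ["2245", "3564", "4113", "5186", "6152", "7271", "8393", "9554", "10685", "11362", "12432", "13542", "14178", "15218", "15940", "16171", "16234"]},
    {"name": "N7", "parent": "N", "motif": ["3588", "5442", "7861", "9872", "11914", "13651", "16215"]},
    {"name": "N8", "parent": "N", "motif": ["1935", "3397", "4715", "6366", "7762", "8836", "10192", "11440", "12771", "13878", "15071", "16258"]},
    {"name": "N9", "parent": "N", "motif": ["5417"]},
    {"name": "N10", "parent": "N", "motif": ["2766", "6158", "10646", "16221"]},
    {"name": "N11", "parent": "N", "motif": ["12950"]},
    {"name": "O/N12", "parent": "N", "motif": ["4136", "8152", "16249"]},
    {"name": "N13", "parent": "N", "motif": ["1664", "2483", "3745", "5027", "6253", "7521", "8715", "9804", "11151", "12358", "13689", "14911", "16293"]},
    {"name": "N21", "parent": "N", "motif": ["1703", "4017", "5301", "7905", "10542", "12634", "16209"]},
    {"name": "N22", "parent": "N", "motif": ["2083", "4391", "6962", "9123", "11253", "13731", "16163"]},
    {"name": "A", "parent": "N", "motif": ["235", "663", "1736", "4248", "4824", "8794", "16290", "16319"]},
    {"name": "S", "parent": "N", "motif": ["8404"]},
    {"name": "X", "parent": "N", "motif": ["6221", "6371", "13966", "14470", "16092", "16255", "16278"]}
  ]
}
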