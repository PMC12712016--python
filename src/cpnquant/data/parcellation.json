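{
 "version": "default-1",
 "areas": [
  {
   "name": "46d",
   "region": "prefrontal"
  },
  {
   "name": "46v",
   "region": "prefrontal"
  },
  {
   "name": "12r",
   "region": "prefrontal"
  },
  {
   "name": "12l",
   "region": "prefrontal"
  },
  {
   "name": "12m",
   "region": "prefrontal"
  },
  {
   "name": "12o",
   "region": "prefrontal"
  },
  {
   "name": "12m/11",
   "region": "prefrontal"
  },
  {
   "name": "45A",
   "region": "prefrontal"
  },
  {
   "name": "45B",
   "region": "prefrontal"
  },
  {
   "name": "9",
   "region": "prefrontal"
  },
  {
   "name": "8B",
   "region": "prefrontal"
  },
  {
   "name": "8A-8r",
   "region": "prefrontal"
  },
  {
   "name": "9/8B",
   "region": "prefrontal"
  },
  {
   "name": "FEF",
   "region": "prefrontal"
  },
  {
   "name": "13",
   "region": "prefrontal"
  },
  {
   "name": "11",
   "region": "prefrontal"
  },
  {
   "name": "14",
   "region": "prefrontal"
  },
  {
   "name": "10",
   "region": "prefrontal"
  },
  {
   "name": "46d (r)",
   "region": "prefrontal",
   "parent": "46d",
   "notes": "injection subfield"
  },
  {
   "name": "46d (i)",
   "region": "prefrontal",
   "parent": "46d",
   "notes": "injection subfield"
  },
  {
   "name": "46d (c)",
   "region": "prefrontal",
   "parent": "46d",
   "notes": "injection subfield"
  },
  {
   "name": "46v (i)",
   "region": "prefrontal",
   "parent": "46v",
   "notes": "injection subfield"
  },
  {
   "name": "12r (r)",
   "region": "prefrontal",
   "parent": "12r",
   "notes": "injection subfield"
  },
  {
   "name": "12r (i)",
   "region": "prefrontal",
   "parent": "12r",
   "notes": "injection subfield"
  },
  {
   "name": "F2",
   "region": "premotor"
  },
  {
   "name": "F2d",
   "region": "premotor"
  },
  {
   "name": "F3",
   "region": "premotor"
  },
  {
   "name": "F4",
   "region": "premotor"
  },
  {
   "name": "F5",
   "region": "premotor"
  },
  {
   "name": "F5a",
   "region": "premotor"
  },
  {
   "name": "F5p",
   "region": "premotor"
  },
  {
   "name": "F6",
   "region": "premotor"
  },
  {
   "name": "F7",
   "region": "premotor"
  },
  {
   "name": "F1",
   "region": "F1",
   "notes": "primary motor; its own region class"
  },
  {
   "name": "GrFO",
   "region": "frontal_opercular"
  },
  {
   "name": "PrCO",
   "region": "frontal_opercular"
  },
  {
   "name": "DO",
   "region": "frontal_opercular"
  },
  {
   "name": "PF",
   "region": "parietal"
  },
  {
   "name": "PFG",
   "region": "parietal"
  },
  {
   "name": "PG",
   "region": "parietal"
  },
  {
   "name": "PGop",
   "region": "parietal"
  },
  {
   "name": "ParOp",
   "region": "parietal"
  },
  {
   "name": "Opt",
   "region": "parietal"
  },
  {
   "name": "AIP",
   "region": "parietal"
  },
  {
   "name": "LIP",
   "region": "parietal"
  },
  {
   "name": "MIP",
   "region": "parietal"
  },
  {
   "name": "VIP",
   "region": "parietal"
  },
  {
   "name": "PE",
   "region": "parietal"
  },
  {
   "name": "PEc",
   "region": "parietal"
  },
  {
   "name": "PEci",
   "region": "parietal"
  },
  {
   "name": "PEip",
   "region": "parietal"
  },
  {
   "name": "PGm",
   "region": "parietal"
  },
  {
   "name": "V6A",
   "region": "parietal"
  },
  {
   "name": "24",
   "region": "cingulate"
  },
  {
   "name": "24c/d",
   "region": "cingulate"
  },
  {
   "name": "23",
   "region": "cingulate"
  },
  {
   "name": "PCC",
   "region": "cingulate"
  },
  {
   "name": "Ins",
   "region": "other"
  },
  {
   "name": "Ia",
   "region": "other"
  },
  {
   "name": "Idg",
   "region": "other"
  },
  {
   "name": "FST",
   "region": "other"
  },
  {
   "name": "MST",
   "region": "other"
  },
  {
   "name": "MT",
   "region": "other"
  },
  {
   "name": "STP",
   "region": "other"
  }
 ]
}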