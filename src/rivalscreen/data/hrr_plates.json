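{
 "description": "Synthetic plate-set fixture mirroring the structure of the AO-HRR pseudoisochromatic series (4 demonstration plates, 14 red-green and 6 tritan test plates). Plate artwork is abstracted away; only the role and confusion axis of each plate matter to the protocol.",
 "plates": [
  {
   "plate_id": "D1",
   "kind": "demonstration"
  },
  {
   "plate_id": "D2",
   "kind": "demonstration"
  },
  {
   "plate_id": "D3",
   "kind": "demonstration"
  },
  {
   "plate_id": "D4",
   "kind": "demonstration"
  },
  {
   "plate_id": "RG1",
   "kind": "test",
   "axis": "red-green"
  },
  {
   "plate_id": "RG2",
   "kind": "test",
   "axis": "red-green"
  },
  {
   "plate_id": "RG3",
   "kind": "test",
   "axis": "red-green"
  },
  {
   "plate_id": "RG4",
   "kind": "test",
   "axis": "red-green"
  },
  {
   "plate_id": "RG5",
   "kind": "test",
   "axis": "red-green"
  },
  {
   "plate_id": "RG6",
   "kind": "test",
   "axis": "red-green"
  },
  {
   "plate_id": "RG7",
   "kind": "test",
   "axis": "red-green"
  },
  {
   "plate_id": "RG8",
   "kind": "test",
   "axis": "red-green"
  },
  {
   "plate_id": "RG9",
   "kind": "test",
   "axis": "red-green"
  },
  {
   "plate_id": "RG10",
   "kind": "test",
   "axis": "red-green"
  },
  {
   "plate_id": "RG11",
   "kind": "test",
   "axis": "red-green"
  },
  {
   "plate_id": "RG12",
   "kind": "test",
   "axis": "red-green"
  },
  {
   "plate_id": "RG13",
   "kind": "test",
   "axis": "red-green"
  },
  {
   "plate_id": "RG14",
   "kind": "test",
   "axis": "red-green"
  },
  {
   "plate_id": "T1",
   "kind": "test",
   "axis": "tritan"
  },
  {
   "plate_id": "T2",
   "kind": "test",
   "axis": "tritan"
  },
  {
   "plate_id": "T3",
   "kind": "test",
   "axis": "tritan"
  },
  {
   "plate_id": "T4",
   "kind": "test",
   "axis": "tritan"
  },
  {
   "plate_id": "T5",
   "kind": "test",
   "axis": "tritan"
  },
  {
   "plate_id": "T6",
   "kind": "test",
   "axis": "tritan"
  }
 ]
}
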