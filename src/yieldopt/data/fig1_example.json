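{
 "constraints": [],
 "metabolites": [
  "S",
  "A",
  "B",
  "C",
  "P",
  "Q"
 ],
 "reactions": [
  {
   "id": "R1",
   "lb": 0.0,
   "reversible": false,
   "stoichiometry": {
    "S": 1.0
   },
   "ub": null
  },
  {
   "id": "R2",
   "lb": 0.0,
   "reversible": false,
   "stoichiometry": {
    "Q": -1.0
   },
   "ub": null
  },
  {
   "id": "R3",
   "lb": 0.0,
   "reversible": false,
   "stoichiometry": {
    "P": -1.0
   },
   "ub": null
  },
  {
   "id": "R4",
   "lb": 0.0,
   "reversible": false,
   "stoichiometry": {
    "B": -1.0
   },
   "ub": null
  },
  {
   "id": "R5",
   "lb": 0.0,
   "reversible": false,
   "stoichiometry": {
    "A": 1.0,
    "S": -1.0
   },
   "ub": null
  },
  {
   "id": "R6",
   "lb": 0.0,
   "reversible": false,
   "stoichiometry": {
    "C": 1.0,
    "P": 1.0,
    "S": -2.0
   },
   "ub": null
  },
  {
   "id": "R7",
   "lb": 0.0,
   "reversible": false,
   "stoichiometry": {
    "A": -1.0,
    "C": 1.0
   },
   "ub": null
  },
  {
   "id": "R8",
   "lb": 0.0,
   "reversible": false,
   "stoichiometry": {
    "Q": 1.0,
    "S": -1.0
   },
   "ub": null
  },
  {
   "id": "R9",
   "lb": 0.0,
   "reversible": false,
   "stoichiometry": {
    "P": 1.0,
    "S": -1.0
   },
   "ub": null
  },
  {
   "id": "R10",
   "lb": 0.0,
   "reversible": false,
   "stoichiometry": {
    "B": 1.0,
    "C": -1.0
   },
   "ub": null
  },
  {
   "id": "R11",
   "lb": null,
   "reversible": true,
   "stoichiometry": {
    "A": -1.0,
    "B": 1.0
   },
   "ub": null
  }
 ]
}
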