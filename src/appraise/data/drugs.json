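{
  "drugs": [
    {"code": "methylphenidate", "name": "Methylphenidate", "drug_class": "stimulant-MPH", "approved_adhd": true,
     "targets": ["dopamine", "norepinephrine"], "modes": ["reuptake_inhibitor", "releaser"], "chemical_family": "phenidate"},
    {"code": "dexmethylphenidate", "name": "Dexmethylphenidate", "drug_class": "stimulant-MPH", "approved_adhd": true,
     "targets": ["dopamine", "norepinephrine"], "modes": ["reuptake_inhibitor", "releaser"], "chemical_family": "phenidate",
     "enantiomer_of": "methylphenidate"},
    {"code": "serdexmethylphenidate", "name": "Serdexmethylphenidate", "drug_class": "stimulant-MPH", "approved_adhd": true,
     "targets": ["dopamine", "norepinephrine"], "modes": ["reuptake_inhibitor", "releaser"], "chemical_family": "phenidate",
     "prodrug_of": "dexmethylphenidate"},
    {"code": "amphetamine", "name": "Amphetamine", "drug_class": "stimulant-AMP", "approved_adhd": true,
     "targets": ["dopamine", "norepinephrine"], "modes": ["reuptake_inhibitor", "releaser"], "chemical_family": "amphetamine"},
    {"code": "dexamphetamine", "name": "Dexamphetamine", "drug_class": "stimulant-AMP", "approved_adhd": true,
     "targets": ["dopamine", "norepinephrine"], "modes": ["reuptake_inhibitor", "releaser"], "chemical_family": "amphetamine",
     "enantiomer_of": "amphetamine"},
    {"code": "lisdexamfetamine", "name": "Lisdexamfetamine", "drug_class": "stimulant-AMP", "approved_adhd": true,
     "targets": ["dopamine", "norepinephrine"], "modes": ["reuptake_inhibitor", "releaser"], "chemical_family": "amphetamine",
     "prodrug_of": "dexamphetamine"},
    {"code": "mixed_amphetamine_salts", "name": "Mixed amphetamine salts", "drug_class": "stimulant-AMP", "approved_adhd": true,
     "targets": ["dopamine", "norepinephrine"], "modes": ["reuptake_inhibitor", "releaser"], "chemical_family": "amphetamine",
     "enantiomer_of": "dexamphetamine"},
    {"code": "atomoxetine", "name": "Atomoxetine", "drug_class": "nonstimulant-NRI", "approved_adhd": true,
     "targets": ["norepinephrine"], "modes": ["reuptake_inhibitor"], "chemical_family": "atomoxetine"},
    {"code": "viloxazine", "name": "Viloxazine", "drug_class": "nonstimulant-NRI", "approved_adhd": true,
     "targets": ["norepinephrine"], "modes": ["reuptake_inhibitor"], "chemical_family": "viloxazine"},
    {"code": "guanfacine", "name": "Guanfacine", "drug_class": "alpha2-agonist", "approved_adhd": true,
     "targets": ["norepinephrine"], "modes": ["receptor_agonist"], "chemical_family": "guanfacine"},
    {"code": "clonidine", "name": "Clonidine", "drug_class": "alpha2-agonist", "approved_adhd": true,
     "targets": ["norepinephrine"], "modes": ["receptor_agonist"], "chemical_family": "clonidine"},
    {"code": "bupropion", "name": "Bupropion", "drug_class": "other", "approved_adhd": false,
     "targets": ["dopamine", "norepinephrine"], "modes": ["reuptake_inhibitor"], "chemical_family": "aminoketone"},
    {"code": "modafinil", "name": "Modafinil", "drug_class": "other", "approved_adhd": false,
     "targets": ["dopamine"], "modes": ["reuptake_inhibitor"], "chemical_family": "benzhydryl"}
  ]
}
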