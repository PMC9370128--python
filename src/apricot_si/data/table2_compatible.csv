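name,country,origin_class,allele1,allele2,flags,source,presumed_homozygous,documented_sc
Big Red,?,unknown,S1,Sc,a,study,0,1
Dama Rosa,?,unknown,S1,Sc,a,study,0,1
Flavorcot,?,unknown,S1,Sc,a,study,0,1
Rojo Pasión,?,unknown,S1,Sc,a,study,0,1
Rubissia,?,unknown,S1,Sc,a,study,0,1
Water,?,unknown,S1,Sc,a;c,study,0,1
Mauricio,?,unknown,S1,Sc,,previous,0,1
Bergecot,?,unknown,S2,Sc,d,study,0,1
Canino,?,unknown,S2,Sc,d,study,0,1
Harval,?,unknown,S2,Sc,a,study,0,1
Justo Cot,?,unknown,S2,Sc,a,study,0,1
Paviot,?,unknown,S2,Sc,d,study,0,1
Primidi,?,unknown,S2,Sc,d,study,0,1
Tilton,?,unknown,S2,Sc,,study,0,1
Berdejo,?,unknown,S2,Sc,,previous,0,1
Bergeron,?,unknown,S2,Sc,,previous,0,1
Budapest,?,unknown,S2,Sc,,previous,0,1
Dulcinea,?,unknown,S2,Sc,,previous,0,1
Galta Vermella Valenciana,?,unknown,S2,Sc,,previous,0,1
Kalao,?,unknown,S2,Sc,,previous,0,1
Konservnyi Pozdnii,?,unknown,S2,Sc,,previous,0,1
Mamaia,?,unknown,S2,Sc,,previous,0,1
Mandulakajszi,?,unknown,S2,Sc,,previous,0,1
Mediva,?,unknown,S2,Sc,,previous,0,1
Peñaflor 02,?,unknown,S2,Sc,,previous,0,1
Pepito del Rubio,?,unknown,S2,Sc,,previous,0,1
Rakovszky,?,unknown,S2,Sc,,previous,0,1
Regibus,?,unknown,S2,Sc,,previous,0,1
Roxana,?,unknown,S2,Sc,,previous,0,1
Rózsakajszi,?,unknown,S2,Sc,,previous,0,1
Sandy cot,?,unknown,S2,Sc,,previous,0,1
Trevatt,?,unknown,S2,Sc,,previous,0,1
Rubista,?,unknown,S3,Sc,d,study,0,1
Pricia,?,unknown,S3,Sc,,previous,0,1
Rambo,?,unknown,S3,Sc,,previous,0,1
Búlida,?,unknown,S5,Sc,,study,0,1
Fartoly,?,unknown,S6,Sc,b;d,study,0,1
Ladycot,?,unknown,S6,Sc,b;d,study,0,1
Medflo,?,unknown,S6,Sc,d,study,0,1
Mediabel,?,unknown,S6,Sc,d,study,0,1
Aprix20,?,unknown,S6,Sc,,previous,0,1
Aprix9,?,unknown,S6,Sc,,previous,0,1
Bebecou,?,unknown,S6,Sc,,previous,0,1
Faralia,?,unknown,S6,Sc,,previous,0,1
Farlis,?,unknown,S6,Sc,,previous,0,1
Lito,?,unknown,S6,Sc,,previous,0,1
Charisma,?,unknown,S7,Sc,d,study,0,1
Ninfa,?,unknown,S7,Sc,,study,0,1
Beliana,?,unknown,S7,Sc,,previous,0,1
Sayeb,?,unknown,S7,Sc,,previous,0,1
Gönci Magyarkajszi,?,unknown,S8,Sc,,study,0,1
Luizet,?,unknown,S8,Sc,b;d,study,0,1
Andornaktályai magyarkajszi,?,unknown,S8,Sc,,previous,0,1
Cacansko zlato,?,unknown,S8,Sc,,previous,0,1
Callatis,?,unknown,S8,Sc,,previous,0,1
Crvena ungarska,?,unknown,S8,Sc,,previous,0,1
Darunec malahoyeva,?,unknown,S8,Sc,,previous,0,1
Effect,?,unknown,S8,Sc,,previous,0,1
Kâsna ungarska,?,unknown,S8,Sc,,previous,0,1
Krimskyi Amur,?,unknown,S8,Sc,,previous,0,1
Nagygyümölcsû magyarkajszi,?,unknown,S8,Sc,,previous,0,1
Nikitskyi,?,unknown,S8,Sc,,previous,0,1
Paksi magyarkajszi,?,unknown,S8,Sc,,previous,0,1
Pisana,?,unknown,S8,Sc,,previous,0,1
Venus,?,unknown,S8,Sc,,previous,0,1
Alba,?,unknown,S9,Sc,a,study,0,1
Aprisweet (ASF0409),?,unknown,S9,Sc,a,study,0,1
Micaelo,?,unknown,S9,Sc,a,study,0,1
Tadeo,?,unknown,S9,Sc,b,study,0,1
AC2,?,unknown,S9,Sc,,previous,0,1
Ceglédi arany,?,unknown,S9,Sc,,previous,0,1
Ceglédi bíborkajski,?,unknown,S9,Sc,,previous,0,1
Flopria,?,unknown,S9,Sc,,previous,0,1
Lido,?,unknown,S9,Sc,,previous,0,1
Tom Cot,?,unknown,S9,Sc,,previous,0,1
Modesto,?,unknown,S13,Sc,,previous,0,1
Mari de Cenad,?,unknown,S19,Sc,,previous,0,1
Cristalí,?,unknown,S20,Sc,,previous,0,1
Gavatxet,?,unknown,S20,Sc,,previous,0,1
Ezzine,?,unknown,S24,Sc,,previous,0,1
Ananasnyi ciurpinskii,?,unknown,Sc,Sc,,previous,0,1
Asli,?,unknown,Sc,Sc,,previous,0,1
Borsi-féle kései rózsa,?,unknown,Sc,Sc,,previous,0,1
Ceglédi kedves,?,unknown,Sc,Sc,,previous,0,1
Currot,?,unknown,Sc,Sc,,previous,0,1
GaltaRoja,?,unknown,Sc,Sc,,previous,0,1
Gandía,?,unknown,Sc,Sc,,previous,0,1
Ginesta,?,unknown,Sc,Sc,,previous,0,1
Grandir,?,unknown,Sc,Sc,,previous,0,1
Manrí,?,unknown,Sc,Sc,,previous,0,1
NJA-8,?,unknown,Sc,Sc,,previous,0,1
Nyujtó Ferenc emléke,?,unknown,Sc,Sc,,previous,0,1
Palabras,?,unknown,Sc,Sc,,previous,0,1
Palau,?,unknown,Sc,Sc,,previous,0,1
Pannónia,?,unknown,Sc,Sc,,previous,0,1
Pasinok,?,unknown,Sc,Sc,,previous,0,1
Patterson,?,unknown,Sc,Sc,,previous,0,1
Raki,?,unknown,Sc,Sc,,previous,0,1
Rojo Carlet,?,unknown,Sc,Sc,,previous,0,1
Sirena,?,unknown,Sc,Sc,,previous,0,1
Sulmona,?,unknown,Sc,Sc,,previous,0,1
Tirynthos,?,unknown,Sc,Sc,,previous,0,1
Xirivello,?,unknown,Sc,Sc,,previous,0,1
Zaposdolye,?,unknown,Sc,Sc,,previous,0,1
Aprix 116,?,unknown,Sc,,a,study,1,1
Cebas Red,?,unknown,Sc,,,study,1,1
Cocot,?,unknown,Sc,,a,study,1,1
Corbato,?,unknown,Sc,,d,study,1,1
Delice cot,?,unknown,Sc,,d,study,1,1
Fantasme,?,unknown,Sc,,a,study,1,1
Farhial,?,unknown,Sc,,d,study,1,1
IPS21512,?,unknown,Sc,,a,study,1,1
IPS2712,?,unknown,Sc,,a,study,1,1
Laguna,?,unknown,Sc,,a,study,1,1
Merino,?,unknown,Sc,,a,study,1,1
Mirlo anaranjado,?,unknown,Sc,,d,study,1,1
Mirlo blanco,?,unknown,Sc,,d,study,1,1
Mirlo Rojo,?,unknown,Sc,,,study,1,1
Mitger,?,unknown,Sc,,d,study,1,1
Orange rubis,?,unknown,Sc,,a,study,1,1
Precoz de Tirynthos,?,unknown,Sc,,a,study,1,1
Primorosa,?,unknown,Sc,,,study,1,1
Soledane,?,unknown,Sc,,d,study,1,1
Tardorange,?,unknown,Sc,,a,study,1,1
Valorange,?,unknown,Sc,,a,study,1,1
Aprix 33,?,unknown,Sc,,,previous,1,1
ASF0404 (Apriqueen),?,unknown,Sc,,,previous,1,1
Dorada,?,unknown,Sc,,,previous,1,1
Faclo,?,unknown,Sc,,,previous,1,1
Farbaly,?,unknown,Sc,,,previous,1,1
Farbela,?,unknown,Sc,,,previous,1,1
Fardao,?,unknown,Sc,,,previous,1,1
Farfia,?,unknown,Sc,,,previous,1,1
Farius,?,unknown,Sc,,,previous,1,1
IBCOT 13-12,?,unknown,Sc,,,previous,1,1
IPS16121,?,unknown,Sc,,,previous,1,1
Kioto,?,unknown,Sc,,,previous,1,1
Memphis,?,unknown,Sc,,,previous,1,1
Milord,?,unknown,Sc,,,previous,1,1
Murciana,?,unknown,Sc,,,previous,1,1
Oscar,?,unknown,Sc,,,previous,1,1
Playa cot,?,unknown,Sc,,,previous,1,1
Rouge cot,?,unknown,Sc,,,previous,1,1
Rubely,?,unknown,Sc,,,previous,1,1
Sherpa,?,unknown,Sc,,,previous,1,1
Swired,?,unknown,Sc,,,previous,1,1
Katy,?,unknown,S1,S2,,study,0,1
Lorna,?,unknown,S1,S2,,previous,0,1
Palsteyn,?,unknown,S1,S2,,previous,0,1
Victor 1,?,unknown,S2,S9,,previous,0,1
IPS20390,?,unknown,S1,,,previous,0,1
Rubilis,?,unknown,S1,,,previous,0,1
Golden Sweet,?,unknown,S3,,,previous,0,1
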