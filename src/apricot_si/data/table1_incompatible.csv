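name,country,origin_class,allele1,allele2,flags,source,presumed_homozygous,documented_sc
AC1,?,unknown,S1,S2,,previous,0,0
Castleton,?,unknown,S1,S2,,previous,0,0
Farmingdale,?,unknown,S1,S2,,previous,0,0
Giovanniello,?,unknown,S1,S2,,previous,0,0
Goldrich,?,unknown,S1,S2,,previous,0,0
Hargrand,?,unknown,S1,S2,,previous,0,0
Lambertin-1,?,unknown,S1,S2,,previous,0,0
Ceglédi óriás,?,unknown,S8,S9,,previous,0,0
Cologlu,?,unknown,S8,S9,,previous,0,0
Ligeti óriás,?,unknown,S8,S9,,previous,0,0
Perlecot,?,unknown,S8,S9,,previous,0,0
Pinkcot,?,unknown,S8,S9,,previous,0,0
Szegedi M.,?,unknown,S8,S9,,previous,0,0
Muñoz,?,unknown,S2,S6,b,study,0,0
Pandora,?,unknown,S2,S6,b,study,0,0
ASF0401,?,unknown,S2,S6,,previous,0,0
Avirine (Bergarouge),?,unknown,S2,S6,,previous,0,0
Moniqui,?,unknown,S2,S6,,previous,0,0
Ouardi,?,unknown,S2,S7,,previous,0,0
Priana,?,unknown,S2,S7,,previous,0,0
Sweet Cot,?,unknown,S2,S8,d,study,0,0
Alyanak,?,unknown,S2,S8,,previous,0,0
Holly Cot,?,unknown,S2,S8,,previous,0,0
Apribang (ASF0405),?,unknown,S6,S9,a,study,0,0
ASF0402,?,unknown,S6,S9,,previous,0,0
Cataloglu,?,unknown,S6,S9,,previous,0,0
Cheyenne,?,unknown,S6,S9,,previous,0,0
Feria Cot,?,unknown,S6,S9,,previous,0,0
Flashcot,?,unknown,S6,S9,,previous,0,0
JNP,?,unknown,S6,S9,,previous,0,0
Ninja,?,unknown,S6,S9,,previous,0,0
Orangered,?,unknown,S6,S9,,previous,0,0
Soganci,?,unknown,S6,S9,,previous,0,0
Stark Early Orange,?,unknown,S6,S9,,previous,0,0
Sunny Cot,?,unknown,S6,S9,,previous,0,0
Wonder Cot,?,unknown,S6,S9,,previous,0,0
Bedri Ahmar,?,unknown,S7,S12,,previous,0,0
Oud Rhayem,?,unknown,S7,S12,,previous,0,0
Haci Haliloglu,?,unknown,S9,S13,,previous,0,0
Kabaasi,?,unknown,S9,S13,,previous,0,0
Voski,?,unknown,S11,S13,,previous,0,0
Levent,?,unknown,S6,S19,,previous,0,0
Oueld El Oud,?,unknown,S7,S8,,previous,0,0
Bouk Ahmed,?,unknown,S7,S11,,previous,0,0
Hamidi,?,unknown,S7,S11,,previous,0,0
Adedi Ahmar,?,unknown,S8,S12,,previous,0,0
IPS23214,?,unknown,S1,S3,a,study,0,0
Monred,?,unknown,S1,S3,a,study,0,0
Cooper Cot,?,unknown,S1,S3,,previous,0,0
Perfection,?,unknown,S1,S3,,previous,0,0
Mayacot,?,unknown,S2,S3,,previous,0,0
Sun Glo,?,unknown,S2,S3,,previous,0,0
Goldstrike 02,?,unknown,S2,S9,,previous,0,0
Hasanbey,?,unknown,S2,S9,,previous,0,0
Magic Cot,?,unknown,S2,S9,,previous,0,0
Samourai,?,unknown,S3,S8,a;c,study,0,0
Lilly Cot,?,unknown,S3,S8,,previous,0,0
Spring Blush,?,unknown,S3,S8,,previous,0,0
Almadulce,?,unknown,S3,S9,,previous,0,0
Flodea,?,unknown,S3,S9,,previous,0,0
Henderson,?,unknown,S3,S9,,previous,0,0
Kosmos,?,unknown,S3,S9,,previous,0,0
Tsunami,?,unknown,S3,S9,,previous,0,0
Goldbar,?,unknown,S7,S9,,previous,0,0
Kurukabuk,?,unknown,S7,S9,,previous,0,0
Primaya,?,unknown,S1,S6,,previous,0,0
Farely,?,unknown,S1,S9,b,study,0,0
Megatea,?,unknown,S1,S9,b,study,0,0
Monster Cot,?,unknown,S1,S9,b,study,0,0
Priabel,?,unknown,S1,S9,b,study,0,0
Almater,?,unknown,S1,S9,,previous,0,0
Aurora,?,unknown,S1,S9,,previous,0,0
Medaga,?,unknown,S1,S9,,previous,0,0
Robada,?,unknown,S6,S8,,previous,0,0
Harcot,?,unknown,S1,S4,b,study,0,0
Bouthani Ben Friha,?,unknown,S12,S13,,previous,0,0
Cow-1,?,unknown,S1,S31,,previous,0,0
Cow-2,?,unknown,S20,S31,,previous,0,0
Estrella,?,unknown,S1,S7,,previous,0,0
Harlayne,?,unknown,S3,S20,,previous,0,0
Harmat,?,unknown,S10,S11,,previous,0,0
Korai zamatos,?,unknown,S12,S13,,previous,0,0
Mariem,?,unknown,S7,S20,,previous,0,0
Martinet,?,unknown,S2,S2,,previous,0,0
Oud Hmida,?,unknown,S2,S12,,previous,0,0
Perla,?,unknown,S2,S20,,previous,0,0
Portici,?,unknown,S2,S20,,previous,0,0
Shalakh (Erevani),?,unknown,S5,S11,,previous,0,0
Velázquez,?,unknown,S5,S20,,previous,0,0
Dama taronja,?,unknown,S1,,a,study,0,0
Tornado,?,unknown,S1,,a,study,0,0
Vitillo,?,unknown,S1,,a,study,0,0
IBCOT 18-2,?,unknown,S1,,,previous,0,0
Fuego,?,unknown,S2,,a,study,0,0
Cyrano,?,unknown,S2,,,previous,0,0
IBCOT 29-5,?,unknown,S2,,,previous,0,0
Veecot,?,unknown,S2,,,previous,0,0
Mogador,?,unknown,S3,,a,study,0,0
Colorado,?,unknown,S3,,,previous,0,0
Mikado,?,unknown,S3,,,previous,0,0
Stella,?,unknown,S6,,,previous,0,0
Vanilla Cot,?,unknown,S8,,,previous,0,0
Goldstrike 01,?,unknown,S9,,,previous,0,0
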