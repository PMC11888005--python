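{
 "names": [
  {
   "name": "Amara Okafor",
   "sex": "female"
  },
  {
   "name": "Sofia Ramirez",
   "sex": "female"
  },
  {
   "name": "Mei-Ling Chen",
   "sex": "female"
  },
  {
   "name": "Priya Sharma",
   "sex": "female"
  },
  {
   "name": "Fatima Al-Rashid",
   "sex": "female"
  },
  {
   "name": "Hannah Goldberg",
   "sex": "female"
  },
  {
   "name": "Keisha Washington",
   "sex": "female"
  },
  {
   "name": "Ingrid Larsen",
   "sex": "female"
  },
  {
   "name": "Yuki Tanaka",
   "sex": "female"
  },
  {
   "name": "Aaliyah Johnson",
   "sex": "female"
  },
  {
   "name": "Noor Hassan",
   "sex": "female"
  },
  {
   "name": "Rosa Delgado",
   "sex": "female"
  },
  {
   "name": "Anya Petrova",
   "sex": "female"
  },
  {
   "name": "Grace Kim",
   "sex": "female"
  },
  {
   "name": "Leilani Kahale",
   "sex": "female"
  },
  {
   "name": "Zara Ahmed",
   "sex": "female"
  },
  {
   "name": "Chiara Rossi",
   "sex": "female"
  },
  {
   "name": "Thandiwe Ndlovu",
   "sex": "female"
  },
  {
   "name": "Maeve O'Connor",
   "sex": "female"
  },
  {
   "name": "Lucia Fernandez",
   "sex": "female"
  },
  {
   "name": "Sarah Miller",
   "sex": "female"
  },
  {
   "name": "Amira Haddad",
   "sex": "female"
  },
  {
   "name": "Ananya Iyer",
   "sex": "female"
  },
  {
   "name": "Esther Cohen",
   "sex": "female"
  },
  {
   "name": "Dominique Laurent",
   "sex": "female"
  },
  {
   "name": "Xiomara Vasquez",
   "sex": "female"
  },
  {
   "name": "Freya Nielsen",
   "sex": "female"
  },
  {
   "name": "Tamar Abramov",
   "sex": "female"
  },
  {
   "name": "Nia Brooks",
   "sex": "female"
  },
  {
   "name": "Svetlana Volkov",
   "sex": "female"
  },
  {
   "name": "Isabella Santos",
   "sex": "female"
  },
  {
   "name": "Jasmine Lee",
   "sex": "female"
  },
  {
   "name": "Aisha Diallo",
   "sex": "female"
  },
  {
   "name": "Margarita Morales",
   "sex": "female"
  },
  {
   "name": "Hye-Jin Park",
   "sex": "female"
  },
  {
   "name": "Siobhan Murphy",
   "sex": "female"
  },
  {
   "name": "Valentina Cruz",
   "sex": "female"
  },
  {
   "name": "Adaeze Eze",
   "sex": "female"
  },
  {
   "name": "Katarzyna Nowak",
   "sex": "female"
  },
  {
   "name": "Mariam Tesfaye",
   "sex": "female"
  },
  {
   "name": "Emily Carter",
   "sex": "female"
  },
  {
   "name": "Linh Nguyen",
   "sex": "female"
  },
  {
   "name": "Paloma Herrera",
   "sex": "female"
  },
  {
   "name": "Rivka Stein",
   "sex": "female"
  },
  {
   "name": "Ayla Demir",
   "sex": "female"
  },
  {
   "name": "Josephine Baptiste",
   "sex": "female"
  },
  {
   "name": "Signe Andersen",
   "sex": "female"
  },
  {
   "name": "Devika Nair",
   "sex": "female"
  },
  {
   "name": "Carmen Ortiz",
   "sex": "female"
  },
  {
   "name": "Naomi Fischer",
   "sex": "female"
  },
  {
   "name": "Mateo Alvarez",
   "sex": "male"
  },
  {
   "name": "Jamal Robinson",
   "sex": "male"
  },
  {
   "name": "Wei Zhang",
   "sex": "male"
  },
  {
   "name": "Arjun Patel",
   "sex": "male"
  },
  {
   "name": "Omar Khalil",
   "sex": "male"
  },
  {
   "name": "David Rosenberg",
   "sex": "male"
  },
  {
   "name": "Marcus Thompson",
   "sex": "male"
  },
  {
   "name": "Lars Eriksen",
   "sex": "male"
  },
  {
   "name": "Hiroshi Yamamoto",
   "sex": "male"
  },
  {
   "name": "Darnell Williams",
   "sex": "male"
  },
  {
   "name": "Tariq Mansour",
   "sex": "male"
  },
  {
   "name": "Diego Gutierrez",
   "sex": "male"
  },
  {
   "name": "Dmitri Sokolov",
   "sex": "male"
  },
  {
   "name": "Min-Jun Choi",
   "sex": "male"
  },
  {
   "name": "Kai Makoa",
   "sex": "male"
  },
  {
   "name": "Hassan Farah",
   "sex": "male"
  },
  {
   "name": "Luca Bianchi",
   "sex": "male"
  },
  {
   "name": "Sipho Dlamini",
   "sex": "male"
  },
  {
   "name": "Liam Gallagher",
   "sex": "male"
  },
  {
   "name": "Javier Mendoza",
   "sex": "male"
  },
  {
   "name": "Daniel Brown",
   "sex": "male"
  },
  {
   "name": "Karim Nasser",
   "sex": "male"
  },
  {
   "name": "Rohan Mehta",
   "sex": "male"
  },
  {
   "name": "Ezra Shapiro",
   "sex": "male"
  },
  {
   "name": "Antoine Dubois",
   "sex": "male"
  },
  {
   "name": "Alejandro Reyes",
   "sex": "male"
  },
  {
   "name": "Bjorn Haugen",
   "sex": "male"
  },
  {
   "name": "Avi Mizrahi",
   "sex": "male"
  },
  {
   "name": "Malik Carter",
   "sex": "male"
  },
  {
   "name": "Nikolai Orlov",
   "sex": "male"
  },
  {
   "name": "Rafael Silva",
   "sex": "male"
  },
  {
   "name": "Kevin Tran",
   "sex": "male"
  },
  {
   "name": "Mamadou Sow",
   "sex": "male"
  },
  {
   "name": "Esteban Rojas",
   "sex": "male"
  },
  {
   "name": "Joon-Ho Kang",
   "sex": "male"
  },
  {
   "name": "Declan Byrne",
   "sex": "male"
  },
  {
   "name": "Andres Castillo",
   "sex": "male"
  },
  {
   "name": "Chinedu Okeke",
   "sex": "male"
  },
  {
   "name": "Piotr Kowalski",
   "sex": "male"
  },
  {
   "name": "Dawit Bekele",
   "sex": "male"
  },
  {
   "name": "Michael Turner",
   "sex": "male"
  },
  {
   "name": "Quan Pham",
   "sex": "male"
  },
  {
   "name": "Santiago Vargas",
   "sex": "male"
  },
  {
   "name": "Moshe Katz",
   "sex": "male"
  },
  {
   "name": "Emre Yilmaz",
   "sex": "male"
  },
  {
   "name": "Jean-Pierre Toussaint",
   "sex": "male"
  },
  {
   "name": "Soren Madsen",
   "sex": "male"
  },
  {
   "name": "Vikram Rao",
   "sex": "male"
  },
  {
   "name": "Felipe Navarro",
   "sex": "male"
  },
  {
   "name": "Jonah Weiss",
   "sex": "male"
  }
 ]
}
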